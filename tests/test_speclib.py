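import numpy as np
import pytest

from oracles import oracle_qvalues
from xenosplit import (
    Fragment,
    LibraryError,
    PSMRecord,
    SpectralLibrary,
    assemble_library,
    calibrate_rt,
    compute_qvalues,
    contribution_analysis,
    filter_fdr,
    library_stats,
    pseudo_reverse_decoy,
    read_library_tsv,
    read_psm_tsv,
    write_library_tsv,
    write_psm_tsv,
)
from xenosplit.speclib import LibraryEntry, RTCalibration


def make_psm(
    peptide="SAMPLEPEPTIDEK",
    run_id="run01",
    charge=2,
    score=10.0,
    is_decoy=False,
    rt=30.0,
    n_fragments=5,
    protein="P1",
    species="mouse",
):
    frags = tuple(
        Fragment("y", i + 1, 1, 200.0 + 10 * i, 100.0 - 10 * i)
        for i in range(n_fragments)
    )
    return PSMRecord(
        run_id=run_id,
        peptide=peptide,
        modified_sequence=peptide,
        charge=charge,
        score=score,
        is_decoy=is_decoy,
        rt=rt,
        fragments=frags,
        protein=protein,
        species=species,
    )


class TestCalibrateRT:
    IRT = {f"PEP{i}K": 10.0 * i for i in range(11)}

    def _run(self, rts, peptides=None):
        peptides = peptides or list(self.IRT)
        return [
            make_psm(peptide=p, rt=rt, score=5.0)
            for p, rt in zip(peptides, rts)
        ]

    def test_exact_linear_fit(self):
        rts = [0.5 * self.IRT[p] + 30.0 for p in self.IRT]
        cal = calibrate_rt(self._run(rts), self.IRT)
        assert cal.slope == pytest.approx(0.5)
        assert cal.intercept == pytest.approx(30.0)
        assert cal.r_squared == pytest.approx(1.0)
        assert not cal.excluded
        assert cal.to_irt(0.5 * 70 + 30) == pytest.approx(70.0)

    def test_poor_fit_excluded(self):
        irt = {"AK": 0.0, "BK": 50.0, "CK": 100.0}
        psms = [make_psm(peptide=p, rt=r) for p, r in zip(irt, [10.0, 60.0, 20.0])]
        cal = calibrate_rt(psms, irt)
        assert cal.r_squared == pytest.approx(0.0357, abs=1e-3)
        assert cal.excluded

    def test_single_irt_peptide_errors(self):
        psms = [make_psm(peptide="PEP0K", rt=30.0)]
        with pytest.raises(LibraryError, match="uncalibratable"):
            calibrate_rt(psms, self.IRT)

    def test_decoys_never_calibrate(self):
        psms = [
            make_psm(peptide="PEP0K", rt=30.0),
            make_psm(peptide="PEP1K", rt=35.0, is_decoy=True),
        ]
        with pytest.raises(LibraryError, match="uncalibratable"):
            calibrate_rt(psms, self.IRT)


class TestQValues:
    def test_counting_example(self):
        scores = [10.0, 9.0, 7.0, 5.0, 8.0, 6.0]
        decoy = [False, False, False, False, True, True]
        q = compute_qvalues(scores, decoy)
        assert q[0] == pytest.approx(0.0, abs=1e-3)
        assert q[1] == pytest.approx(0.0, abs=1e-3)
        assert q[2] == pytest.approx(1 / 3, abs=1e-3)
        assert q[3] == pytest.approx(0.5, abs=1e-3)
        assert np.isnan(q[4]) and np.isnan(q[5])

    def test_targets_above_best_decoy_have_zero_q(self):
        scores = [10.0, 9.0, 8.0, 3.0, 2.0]
        decoy = [False, False, False, True, True]
        q = compute_qvalues(scores, decoy)
        assert np.allclose(q[:3], 0.0)

    def test_matches_bruteforce_oracle_on_random_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = np.round(rng.normal(0, 1, size=n), 2)  # rounding forces ties
            decoy = rng.random(n) < 0.5
            if decoy.all() or not decoy.any():
                continue
            got = compute_qvalues(scores, decoy)
            expected = oracle_qvalues(scores, decoy)
            assert np.allclose(got[~decoy], expected[~decoy])

    def test_monotone_nonincreasing_in_score(self):
        rng = np.random.default_rng(23)
        scores = rng.normal(0, 1, 500)
        decoy = rng.random(500) < 0.5
        q = compute_qvalues(scores, decoy)
        t = ~decoy
        order = np.argsort(scores[t])
        assert np.all(np.diff(q[t][order]) <= 1e-12)
        assert np.nanmin(q) >= 0 and np.nanmax(q[t]) <= 1

    def test_no_decoys_errors(self):
        with pytest.raises(LibraryError):
            compute_qvalues([1.0, 2.0], [False, False])


class TestFilterFDR:
    def test_peptide_threshold(self):
        # decoy at 8 makes the two low targets fail q<=0.01
        psms = [
            make_psm(score=10.0, peptide="AAAAAAAK", protein="P1"),
            make_psm(score=9.0, peptide="CCCCCCCK", protein="P2"),
            make_psm(score=8.0, peptide="DDDDDDDK", protein="D1", is_decoy=True),
            make_psm(score=7.0, peptide="EEEEEEEK", protein="P3"),
        ]
        kept = filter_fdr(psms)
        assert {p.peptide for p in kept} == {"AAAAAAAK", "CCCCCCCK"}

    def test_two_stage_subset_of_peptide_only(self):
        rng = np.random.default_rng(31)
        psms = []
        for i in range(200):
            is_decoy = bool(rng.random() < 0.5)
            psms.append(
                make_psm(
                    peptide=f"PEPTIDE{i}K",
                    protein=f"{'D' if is_decoy else 'P'}{i % 40}",
                    score=float(rng.normal(3.0 if not is_decoy else 0.0, 1.0)),
                    is_decoy=is_decoy,
                )
            )
        q = compute_qvalues([p.score for p in psms], [p.is_decoy for p in psms])
        peptide_only = {
            id(p) for p, qv in zip(psms, q) if not p.is_decoy and qv <= 0.01
        }
        two_stage = {id(p) for p in filter_fdr(psms)}
        assert two_stage <= peptide_only


class TestAssembleLibrary:
    CAL = {
        "run01": RTCalibration("run01", 0.5, 10.0, 1.0, 11, False),
        "run02": RTCalibration("run02", 1.0, 0.0, 1.0, 11, False),
        "bad": RTCalibration("bad", 1.0, 0.0, 0.5, 11, True),
    }

    def test_top6_transitions_rescaled(self):
        psm = make_psm(n_fragments=10)
        lib = assemble_library([psm], self.CAL)
        (entry,) = lib.entries
        assert len(entry.transitions) == 6
        assert entry.transitions[0].intensity == pytest.approx(1.0)
        intens = [t.intensity for t in entry.transitions]
        assert intens == sorted(intens, reverse=True)

    def test_min_three_fragments_enforced(self):
        lib = assemble_library([make_psm(n_fragments=2)], self.CAL)
        assert len(lib) == 0

    def test_representative_is_best_scoring_run(self):
        psms = [
            make_psm(run_id="run01", score=20.0, rt=40.0, n_fragments=4),
            make_psm(run_id="run02", score=40.0, rt=55.0, n_fragments=5),
            make_psm(run_id="run01", score=30.0, rt=42.0, n_fragments=3),
        ]
        lib = assemble_library(psms, self.CAL)
        (entry,) = lib.entries
        assert len(entry.transitions) == 5  # from the score-40 PSM
        assert entry.irt == pytest.approx(55.0)  # run02 calibration: identity

    def test_excluded_run_skipped(self):
        psms = [make_psm(run_id="bad", score=99.0)]
        lib = assemble_library(psms, self.CAL)
        assert len(lib) == 0

    def test_intensity_tie_broken_by_lower_mz(self):
        frags = (
            Fragment("y", 1, 1, 400.0, 50.0),
            Fragment("y", 2, 1, 300.0, 50.0),
            Fragment("y", 3, 1, 500.0, 80.0),
        )
        psm = make_psm()
        psm = PSMRecord(**{**psm.__dict__, "fragments": frags})
        lib = assemble_library([psm], self.CAL)
        (entry,) = lib.entries
        assert [t.mz for t in entry.transitions] == [500.0, 300.0, 400.0]

    def test_entry_invariants_enforced(self):
        frags = tuple(Fragment("y", i + 1, 1, 200.0, 1.0) for i in range(2))
        with pytest.raises(LibraryError, match="transitions"):
            LibraryEntry(
                modified_sequence="AAK", peptide="AAK", charge=2,
                precursor_mz=100.0, irt=5.0, protein="P1", species="m",
                transitions=frags,
            )
        with pytest.raises(LibraryError, match="duplicate"):
            psm = make_psm(n_fragments=4)
            lib = assemble_library([psm], self.CAL)
            SpectralLibrary(entries=lib.entries + lib.entries)


class TestLibraryIO:
    def test_round_trip(self, tmp_path):
        psms = [
            make_psm(peptide="AAAAAAAK", protein="P1", n_fragments=4),
            make_psm(peptide="CCCCCCCK", protein="P2", n_fragments=6, charge=3),
        ]
        cal = {"run01": RTCalibration("run01", 1.0, 0.0, 1.0, 11, False)}
        lib = assemble_library(psms, cal)
        path = tmp_path / "lib.tsv"
        write_library_tsv(lib, path)
        back = read_library_tsv(path)
        assert len(back) == len(lib)
        for a, b in zip(
            sorted(lib.entries, key=lambda e: (e.modified_sequence, e.charge)),
            sorted(back.entries, key=lambda e: (e.modified_sequence, e.charge)),
        ):
            assert a.modified_sequence == b.modified_sequence
            assert a.charge == b.charge
            assert a.precursor_mz == pytest.approx(b.precursor_mz, abs=1e-6)
            assert a.irt == pytest.approx(b.irt, abs=1e-6)
            assert len(a.transitions) == len(b.transitions)

    def test_missing_column_errors(self, tmp_path):
        psms = [make_psm(n_fragments=4)]
        cal = {"run01": RTCalibration("run01", 1.0, 0.0, 1.0, 11, False)}
        path = tmp_path / "lib.tsv"
        write_library_tsv(assemble_library(psms, cal), path)
        import pandas as pd

        df = pd.read_csv(path, sep="\t").drop(columns=["ProductMz"])
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(LibraryError, match="ProductMz"):
            read_library_tsv(path)

    def test_row_count_is_total_transitions(self, tmp_path):
        psms = [
            make_psm(peptide="AAAAAAAK", protein="P1", n_fragments=4),
            make_psm(peptide="CCCCCCCK", protein="P2", n_fragments=9),
        ]
        cal = {"run01": RTCalibration("run01", 1.0, 0.0, 1.0, 11, False)}
        lib = assemble_library(psms, cal)
        path = tmp_path / "lib.tsv"
        write_library_tsv(lib, path)
        import pandas as pd

        assert len(pd.read_csv(path, sep="\t")) == sum(
            len(e.transitions) for e in lib.entries
        )

    def test_psm_round_trip(self, tmp_path):
        psms = [make_psm(), make_psm(peptide="CCCCCCCK", is_decoy=True, species="")]
        path = tmp_path / "psms.tsv"
        write_psm_tsv(psms, path)
        back = read_psm_tsv(path)
        assert len(back) == 2
        assert back[0].peptide == psms[0].peptide
        assert back[1].is_decoy
        assert back[0].fragments[0].mz == pytest.approx(psms[0].fragments[0].mz)


class TestLibraryStats:
    def _library(self, peptides_per_protein):
        entries = []
        cal = {"run01": RTCalibration("run01", 1.0, 0.0, 1.0, 11, False)}
        psms = []
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for p, (prot, n) in enumerate(peptides_per_protein.items()):
            for i in range(n):
                psms.append(
                    make_psm(peptide=f"PEP{aa[p]}W{aa[i]}K", protein=prot, n_fragments=4)
                )
        return assemble_library(psms, cal)

    def test_fractions(self):
        lib = self._library({"P1": 5, "P2": 1, "P3": 12})
        stats = library_stats(lib)
        assert stats["n_proteins"] == 3
        assert stats["frac_gt1_peptide"] == pytest.approx(2 / 3)
        assert stats["frac_gt10_peptides"] == pytest.approx(1 / 3)

    def test_coverage(self):
        lib = self._library({"P1": 1, "P2": 1, "P3": 1})
        assert library_stats(lib, annotated_proteome_size=10)["coverage_pct"] == pytest.approx(30.0)

    def test_empty_library_errors(self):
        with pytest.raises(LibraryError):
            library_stats(SpectralLibrary(entries=[]))


class TestContribution:
    def test_in_all_and_exclusive(self):
        sets = {"S1": {"p1", "p2"}, "S2": {"p1", "p3"}, "S3": {"p1"}}
        result = contribution_analysis(sets)
        assert result["in_all"] == {"p1"}
        assert result["exclusive"] == {"S1": {"p2"}, "S2": {"p3"}, "S3": set()}

    def test_single_set(self):
        result = contribution_analysis({"S1": {"a", "b"}})
        assert result["in_all"] == {"a", "b"}
        assert result["exclusive"]["S1"] == {"a", "b"}

    def test_lattice_partitions_union(self):
        rng = np.random.default_rng(13)
        universe = [f"p{i}" for i in range(50)]
        sets = {
            f"S{j}": {p for p in universe if rng.random() < 0.4} for j in range(4)
        }
        sets = {k: v for k, v in sets.items() if v}
        result = contribution_analysis(sets)
        total = sum(len(v) for v in result["lattice"].values())
        assert total == result["union_size"]
        # membership patterns are disjoint by construction; verify brute force
        union = set().union(*sets.values())
        for item in union:
            pattern = frozenset(k for k, v in sets.items() if item in v)
            assert item in result["lattice"][pattern]


def test_pseudo_reverse_decoy_keeps_cterm():
    assert pseudo_reverse_decoy("ABCDEK") == "EDCBAK"
    assert pseudo_reverse_decoy("AK") == "AK"
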