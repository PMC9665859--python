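"""Genome scan, QTL selection and kinship construction."""

import numpy as np
import pandas as pd
import pytest

import mppqtl as m
from mppqtl.core import EvalGrid, InputError
from mppqtl.ibd import IbdResult
from mppqtl.scan import ScanProfile, kinship_from_ibd, select_qtl


def _profile(rows):
    return ScanProfile(
        pd.DataFrame(rows, columns=["chromosome", "position", "lrt", "p",
                                    "minus_log10_p"])
    )


class TestKinship:
    def _toy_ibd(self):
        # single position, 3 DH genotypes with exact origins:
        # g1,g2 fully from P1; g3 fully from P2
        grid = EvalGrid(("1",), (0.0,), (True,))
        counts = np.array([[[2.0, 0.0]], [[2.0, 0.0]], [[0.0, 2.0]]])
        return IbdResult(("g1", "g2", "g3"), grid, ("P1", "P2"), counts)

    def test_identical_profiles_identical_rows(self):
        K = kinship_from_ibd(self._toy_ibd())
        assert np.allclose(K[0], K[1])
        assert np.allclose(K[:, 0], K[:, 1])

    def test_toy_hand_computation(self):
        """K proportional to origin agreement: M M'/2 gives 2 for same
        origin, 0 for different; diag already 2 so rescaling to unit
        mean diagonal divides by 2."""
        K = kinship_from_ibd(self._toy_ibd())
        expect = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        assert np.allclose(K, expect)

    def test_symmetric_psd(self, rng, dh_nam):
        design, gmap, markers, truth, pheno = dh_nam
        ibd = m.calc_ibd_mpp(gmap, markers, design, step_cM=5.0)
        K = kinship_from_ibd(ibd)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8
        assert np.mean(np.diag(K)) == pytest.approx(1.0)

    def test_loco_excludes_chromosome(self, dh_nam):
        design, gmap, markers, truth, pheno = dh_nam
        ibd = m.calc_ibd_mpp(gmap, markers, design, step_cM=5.0)
        K_all = kinship_from_ibd(ibd)
        K_loco = kinship_from_ibd(ibd, exclude_chromosome="1")
        assert not np.allclose(K_all, K_loco)


class TestSelectQtl:
    def test_all_below_threshold_returns_none(self):
        prof = _profile([("1", p, 1.0, 0.3, 0.5) for p in (0.0, 10.0)])
        assert select_qtl(prof, [], threshold=3.0, window_cM=10.0) is None

    def test_unique_peak_selected(self):
        prof = _profile(
            [("1", 30.0, 1, 0.1, 1.0), ("1", 40.0, 20, 1e-7, 6.2),
             ("1", 50.0, 1, 0.1, 1.0)]
        )
        chrom, pos, idx, mlp = select_qtl(prof, [], threshold=3.0, window_cM=10.0)
        assert (chrom, pos, mlp) == ("1", 40.0, 6.2)

    def test_window_exclusion_returns_next_best(self):
        prof = _profile(
            [("1", 38.0, 5, 1e-3, 3.2), ("1", 42.0, 30, 1e-8, 7.5),
             ("2", 10.0, 18, 1e-6, 5.4)]
        )
        got = select_qtl(prof, [("1", 38.0)], threshold=3.0, window_cM=10.0)
        assert got is not None
        assert (got[0], got[1]) == ("2", 10.0)

    def test_tie_breaks_by_chromosome_then_position(self):
        prof = _profile(
            [("1", 20.0, 20, 1e-6, 5.0), ("1", 5.0, 20, 1e-6, 5.0),
             ("2", 1.0, 20, 1e-6, 5.0)]
        )
        got = select_qtl(prof, [], threshold=3.0, window_cM=10.0)
        assert (got[0], got[1]) == ("1", 5.0)


class TestScanGenome:
    def test_one_row_per_grid_position(self, dh_nam):
        design, gmap, markers, truth, pheno = dh_nam
        ibd = m.calc_ibd_mpp(gmap, markers, design, step_cM=5.0)
        prof = m.scan_genome(ibd, pheno, design)
        assert len(prof.frame) == ibd.grid.n_positions
        assert np.all(prof.minus_log10_p >= 0)

    def test_missing_phenotypes_dropped(self, dh_nam):
        design, gmap, markers, truth, pheno = dh_nam
        ibd = m.calc_ibd_mpp(gmap, markers, design, step_cM=10.0)
        pheno2 = pheno.copy()
        pheno2.iloc[:5] = np.nan
        prof = m.scan_genome(ibd, pheno2, design)
        assert len(prof.frame) == ibd.grid.n_positions

    def test_no_phenotype_overlap_raises(self, dh_nam):
        design, gmap, markers, truth, pheno = dh_nam
        ibd = m.calc_ibd_mpp(gmap, markers, design, step_cM=10.0)
        bad = pd.Series([1.0], index=["nobody"])
        with pytest.raises(InputError, match="overlap"):
            m.scan_genome(ibd, bad, design)

    def test_null_phenotype_rarely_exceeds_three(self):
        """Pure-noise phenotypes: -log10(p) exceeds 3 in at most 2 of 20
        replicate scans of a ~100-position grid."""
        rng = np.random.default_rng(1)
        design, gmap, markers, truth, _ = m.nam_dh_scenario(
            rng, n_families=2, n_per_family=100,
            chrom_lengths={"1": 120.0}, marker_step=5.0, qtl_positions=[],
        )
        ibd = m.calc_ibd_mpp(gmap, markers, design, step_cM=1.25)  # 97 positions
        assert ibd.grid.n_positions >= 90
        exceed = 0
        for _ in range(20):
            y = pd.Series(rng.normal(size=200), index=list(design.genotype_ids))
            prof = m.scan_genome(ibd, y, design)
            if prof.minus_log10_p.max() > 3.0:
                exceed += 1
        assert exceed <= 2

    def test_single_qtl_peak_near_truth(self):
        rng = np.random.default_rng(5)
        design, gmap, markers, truth, y = m.nam_dh_scenario(
            rng, n_families=1, n_per_family=150,
            chrom_lengths={"1": 80.0}, marker_step=2.0,
            qtl_positions=[("1", 35.0)], qtl_variance_share=0.5,
        )
        ibd = m.calc_ibd_mpp(gmap, markers, design, step_cM=5.0)
        pheno = pd.Series(y, index=list(design.genotype_ids))
        prof = m.scan_genome(ibd, pheno, design)
        peak = prof.peak()
        assert abs(peak["position"] - 35.0) <= 10.0


class TestMultiRound:
    def test_null_phenotype_stops_immediately(self, dh_nam):
        rng = np.random.default_rng(2)
        design, gmap, markers, truth, pheno = dh_nam
        ibd = m.calc_ibd_mpp(gmap, markers, design, step_cM=10.0)
        noise = pd.Series(
            rng.normal(size=len(pheno)), index=pheno.index
        )
        model = m.multi_round_scan(ibd, noise, design, threshold=5.0)
        assert model.qtls == []
        assert model.n_rounds == 1

    def test_two_unlinked_qtls_recovered(self):
        rng = np.random.default_rng(9)
        design, gmap, markers, truth, y = m.nam_dh_scenario(
            rng, n_families=3, n_per_family=150,
            chrom_lengths={"1": 80.0, "2": 80.0}, marker_step=2.0,
            qtl_positions=[("1", 35.0), ("2", 45.0)], qtl_variance_share=0.3,
        )
        ibd = m.calc_ibd_mpp(gmap, markers, design, step_cM=5.0)
        pheno = pd.Series(y, index=list(design.genotype_ids))
        model = m.multi_round_scan(ibd, pheno, design, max_qtl=5)
        assert len(model.qtls) == 2
        found = {q.chromosome: q.position_cM for q in model.qtls}
        assert abs(found["1"] - 35.0) <= 10.0
        assert abs(found["2"] - 45.0) <= 10.0
        # per-parent effects reported with SEs for each QTL
        assert len(model.effects) == 2 * design.n_founders
        assert (model.effects["se"] > 0).all()

    def test_max_qtl_cap_respected(self):
        rng = np.random.default_rng(9)
        design, gmap, markers, truth, y = m.nam_dh_scenario(
            rng, n_families=3, n_per_family=150,
            chrom_lengths={"1": 80.0, "2": 80.0}, marker_step=2.0,
            qtl_positions=[("1", 35.0), ("2", 45.0)], qtl_variance_share=0.3,
        )
        ibd = m.calc_ibd_mpp(gmap, markers, design, step_cM=5.0)
        pheno = pd.Series(y, index=list(design.genotype_ids))
        model = m.multi_round_scan(ibd, pheno, design, max_qtl=1)
        assert len(model.qtls) == 1

    def test_selected_qtls_respect_window(self):
        rng = np.random.default_rng(9)
        design, gmap, markers, truth, y = m.nam_dh_scenario(
            rng, n_families=2, n_per_family=120,
            chrom_lengths={"1": 80.0}, marker_step=2.0,
            qtl_positions=[("1", 35.0)], qtl_variance_share=0.5,
        )
        ibd = m.calc_ibd_mpp(gmap, markers, design, step_cM=5.0)
        pheno = pd.Series(y, index=list(design.genotype_ids))
        model = m.multi_round_scan(ibd, pheno, design, window_cM=10.0)
        for i, a in enumerate(model.qtls):
            for b in model.qtls[i + 1:]:
                if a.chromosome == b.chromosome:
                    assert abs(a.position_cM - b.position_cM) >= 10.0

    def test_cofactor_drop_reproduces_round1_peak(self):
        """Round-2 profile at a selected QTL's own position (cofactor
        dropped and refit) stays within 0.5 -log10 units of the round-1
        peak."""
        rng = np.random.default_rng(12)
        design, gmap, markers, truth, y = m.nam_dh_scenario(
            rng, n_families=2, n_per_family=120,
            chrom_lengths={"1": 60.0, "2": 60.0}, marker_step=2.0,
            qtl_positions=[("1", 25.0)], qtl_variance_share=0.4,
        )
        ibd = m.calc_ibd_mpp(gmap, markers, design, step_cM=5.0)
        pheno = pd.Series(y, index=list(design.genotype_ids))
        prof1 = m.scan_genome(ibd, pheno, design)
        sel = select_qtl(prof1, [], threshold=3.0, window_cM=10.0)
        assert sel is not None
        _, _, idx, mlp1 = sel
        prof2 = m.scan_genome(ibd, pheno, design, cofactor_indices=[idx])
        mlp2 = prof2.frame.iloc[idx]["minus_log10_p"]
        assert abs(mlp1 - mlp2) <= 0.5

    def test_scan_is_deterministic(self, dh_nam):
        design, gmap, markers, truth, pheno = dh_nam
        ibd = m.calc_ibd_mpp(gmap, markers, design, step_cM=10.0)
        p1 = m.scan_genome(ibd, pheno, design)
        p2 = m.scan_genome(ibd, pheno, design)
        pd.testing.assert_frame_equal(p1.frame, p2.frame)

    def test_kinship_does_not_inflate_null(self):
        """With a family-structure confound (family intercepts far apart)
        and pure-noise within-family phenotypes, turning kinship on does
        not increase the null exceedance count."""
        rng = np.random.default_rng(21)
        design, gmap, markers, truth, _ = m.nam_dh_scenario(
            rng, n_families=3, n_per_family=60,
            chrom_lengths={"1": 60.0, "2": 60.0}, marker_step=5.0,
            qtl_positions=[],
        )
        ibd = m.calc_ibd_mpp(gmap, markers, design, step_cM=10.0)
        exceed_off = exceed_on = 0
        for _ in range(5):
            noise = rng.normal(size=180)
            fam_shift = np.repeat([0.0, 50.0, 100.0], 60)
            y = pd.Series(noise + fam_shift, index=list(design.genotype_ids))
            off = m.scan_genome(ibd, y, design, use_kinship=False)
            on = m.scan_genome(ibd, y, design, use_kinship=True)
            exceed_off += int((off.minus_log10_p > 3).sum())
            exceed_on += int((on.minus_log10_p > 3).sum())
        assert exceed_on <= exceed_off
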