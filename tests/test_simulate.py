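import numpy as np
import pandas as pd
import pytest

from riboscreen.annotation import read_annotation, select_primary
from riboscreen.io_tables import SampleSheet, read_alignments, read_counts, read_gmt
from riboscreen.quantify import assign_psites, occupancy_matrix, region_counts
from riboscreen.simulate import (SimParams, SimulatedScreen, make_guide_pools,
                                 simulate_screen, simulate_transcriptome,
                                 write_fixtures)


class TestSimParams:
    def test_too_few_genes_refused(self):
        with pytest.raises(ValueError, match="n_genes"):
            simulate_transcriptome(SimParams(n_genes=5))

    def test_bad_dispersion_refused(self):
        with pytest.raises(ValueError, match="dispersion"):
            SimParams(dispersion=0).validate()

    def test_effect_fractions_bounded(self):
        with pytest.raises(ValueError, match="fractions"):
            SimParams(frac_te=0.6, frac_rna=0.6).validate()


class TestTranscriptomeGenerator:
    def test_all_null_truth_is_neutral(self, null_sim):
        t = null_sim.truth
        assert (t["true_logFC_RNA"] == 0).all()
        assert (t["true_logFC_TE"] == 0).all()
        assert (t["true_s2b_shift"] == 1).all()
        assert (t["true_uORF_shift"] == 1).all()

    def test_spiked_fractions_match_request_exactly(self, small_sim):
        p, t = small_sim.params, small_sim.truth
        assert (t["true_logFC_TE"] != 0).sum() == round(p.frac_te * p.n_genes)
        assert (t["true_s2b_shift"] != 1).sum() == round(p.frac_s2b * p.n_genes)
        # spiked classes are disjoint
        spiked = ((t["true_logFC_TE"] != 0).astype(int)
                  + (t["true_s2b_shift"] != 1).astype(int)
                  + (t["true_uORF_shift"] != 1).astype(int)
                  + (t["true_logFC_RNA"] != 0).astype(int))
        assert spiked.max() <= 1

    def test_fixed_seed_reproducible(self):
        p = SimParams(n_genes=40, seed=123)
        s1, s2 = simulate_transcriptome(p), simulate_transcriptome(p)
        pd.testing.assert_frame_equal(s1.rna_counts, s2.rna_counts)
        sample = s1.sheet.subset(assay="RPF").sample_ids[0]
        for tid in s1.profiles[sample]:
            np.testing.assert_array_equal(s1.profiles[sample][tid].counts,
                                          s2.profiles[sample][tid].counts)

    def test_profiles_partition_and_lengths(self, small_sim):
        sample = small_sim.sheet.subset(assay="RPF").sample_ids[0]
        for gene, model in list(small_sim.models.items())[:20]:
            prof = small_sim.profiles[sample][model.transcript_id]
            assert prof.counts.size == model.tx_len
            rc = region_counts(prof, model)
            assert rc.total == prof.total

    def test_s2b_shift_reflected_in_density_ratio_at_high_depth(self):
        """Law-of-large-numbers check: at 100x depth the empirical
        start:body density ratio of an s2b-spiked gene is ~shift x the
        null genes' ratio, within 5%."""
        p = SimParams(n_genes=60, seed=3, frac_te=0, frac_uorf=0, frac_rna=0,
                      frac_s2b=0.1, s2b_shift=4.0, frac_short_cds=0,
                      log_mean_expression=np.log(30000.0),
                      sigma_expression=0.2, dispersion=1e-4)
        sim = simulate_transcriptome(p)
        occ = sim.occupancy(s2b_min_rpf=1)
        eff = occ[occ["sample_id"].str.startswith(p.effect_condition)]
        truth = sim.truth.set_index("gene_id")
        dens_ratio = (occ_ratio := (eff.set_index("gene_id")))
        up = truth[truth["true_s2b_shift"] > 1].index
        null = truth[truth["true_s2b_shift"] == 1].index
        ratio = (dens_ratio["cds_start"] / 90) / \
            (dens_ratio["cds_body"] / (dens_ratio["cds_len"] - 90))
        fold = ratio.loc[up].groupby(level=0).mean().mean() / \
            ratio.loc[null].groupby(level=0).mean().mean()
        assert fold == pytest.approx(4.0, rel=0.05)

    def test_nb_counts_are_overdispersed(self, null_sim):
        mat = null_sim.rna_counts.to_numpy(float)
        mean = mat.mean(axis=1)
        var = mat.var(axis=1, ddof=1)
        big = mean > 200
        assert (var[big] > mean[big]).mean() > 0.8


class TestScreenGenerator:
    def _lib(self, n_genes=40):
        rows = []
        for g in range(n_genes):
            for k in range(5):
                rows.append({"guide_id": f"g{g}_q{k}", "gene_id": f"g{g}",
                             "class": "targeting"})
        for k in range(60):
            rows.append({"guide_id": f"nt{k}", "gene_id": "NONTARGETING",
                         "class": "nontargeting"})
        return pd.DataFrame(rows)

    def test_expected_t0_depth_tracks_coverage(self):
        lib = self._lib()
        scr = simulate_screen(lib, coverage=600, seed=0)
        n_guides = len(lib)
        for col in [c for c in scr.counts if c.startswith("T0")]:
            depth = scr.counts[col].sum()
            assert 0.8 * 600 * n_guides <= depth <= 1.2 * 600 * n_guides

    def test_essential_guides_deplete_relative_to_nontargeting(self):
        lib = self._lib()
        scr = simulate_screen(lib, dropout_effect=3.0, n_essential=8, seed=1)
        ess = set(scr.truth.loc[scr.truth["is_dropout_essential"], "gene_id"])
        counts = scr.counts
        ratio = (counts.filter(like="END").sum(axis=1) + 1) / \
            (counts.filter(like="T0").sum(axis=1) + 1)
        gene = lib.set_index("guide_id")["gene_id"]
        ess_ratio = ratio[gene.isin(ess).to_numpy()].median()
        nt_ratio = ratio[(gene == "NONTARGETING").to_numpy()].median()
        assert ess_ratio < 0.3 * nt_ratio

    def test_zero_essentials_exchangeable_with_t0(self):
        lib = self._lib()
        scr = simulate_screen(lib, essential_genes=[], seed=2)
        ratio = scr.counts.filter(like="END").sum(axis=1).sum() / \
            scr.counts.filter(like="T0").sum(axis=1).sum()
        assert ratio == pytest.approx(1.0, rel=0.25)

    def test_invalid_params_refused(self):
        lib = self._lib()
        with pytest.raises(ValueError, match="dropout"):
            simulate_screen(lib, dropout_effect=0)
        with pytest.raises(ValueError, match="coverage"):
            simulate_screen(lib, coverage=10)
        with pytest.raises(ValueError, match="empty"):
            simulate_screen(lib.iloc[:0])

    def test_fixed_seed_reproducible(self):
        lib = self._lib()
        s1 = simulate_screen(lib, seed=9)
        s2 = simulate_screen(lib, seed=9)
        pd.testing.assert_frame_equal(s1.counts, s2.counts)


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    sim = simulate_transcriptome(SimParams(n_genes=50, seed=21))
    out = tmp_path_factory.mktemp("fx")
    paths = write_fixtures(sim, out)
    return sim, paths


class TestFixtures:
    def test_annotation_round_trip_through_gtf(self, fixture_dir):
        sim, paths = fixture_dir
        recs = read_annotation(paths["annotation"])
        assert recs == sim.records
        assert select_primary(recs).keys() == sim.models.keys()

    def test_rna_counts_round_trip(self, fixture_dir):
        sim, paths = fixture_dir
        sheet = SampleSheet.read(paths["sample_sheet"])
        back = read_counts(paths["rna_counts"], sheet.subset(assay="RNA"))
        back.index = back.index.get_level_values(0)
        pd.testing.assert_frame_equal(
            back, sim.rna_counts.rename_axis(index="gene_id"),
            check_dtype=False)

    def test_alignments_reproduce_profiles(self, fixture_dir):
        sim, paths = fixture_dir
        sample = sim.sheet.subset(assay="RPF").sample_ids[0]
        aln = read_alignments(paths[f"alignments_{sample}"])
        tx_lengths = {t: r.tx_len for t, r in sim.records.items()}
        profs = assign_psites(aln, tx_lengths,
                              offset=sim.params.psite_offset)
        for tid, prof in sim.profiles[sample].items():
            np.testing.assert_array_equal(profs[tid].counts, prof.counts)

    def test_gmt_has_te_spiked_set(self, fixture_dir):
        sim, paths = fixture_dir
        sets = read_gmt(paths["gene_sets"])
        up = set(sim.truth.loc[sim.truth["true_logFC_TE"] > 0, "gene_id"])
        assert set(sets["OXPHOS_LIKE"]) == up

    def test_regeneration_is_byte_identical(self, tmp_path):
        import filecmp
        sim = simulate_transcriptome(SimParams(n_genes=30, seed=8))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_fixtures(sim, d1)
        p2 = write_fixtures(simulate_transcriptome(SimParams(n_genes=30, seed=8)),
                            d2)
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key


def test_guide_pools_cover_all_regions(small_sim):
    pools = make_guide_pools(small_sim.models, seed=1, n_per_pool=4)
    assert set(pools["region"]) == {"CDS", "UTR5", "UP"}
    per = pools.groupby(["gene_id", "region"]).size()
    assert (per == 4).all()
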