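import numpy as np
import pandas as pd
import pytest
from conftest import make_truth

from nmdkit.de import CONTROL, NULL
from nmdkit.features import (
    FeatureConfig,
    annotate_transcripts,
    collapse_to_gene,
    detect_dej,
    write_fasta,
    write_gtf,
)
from nmdkit.simulate import (
    SimulationParams,
    expected_count_means,
    simulate_annotation,
    simulate_counts,
    simulate_isoform_tpm,
    simulate_stage_matrix,
)


class TestParams:
    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError):
            SimulationParams(alpha=0.0)

    def test_rejects_bad_feedback(self):
        with pytest.raises(ValueError):
            SimulationParams(feedback_fraction=1.5)

    def test_rejects_tiny_groups(self):
        with pytest.raises(ValueError):
            SimulationParams(n_null=1)

    def test_rejects_dej_on_single_exon_annotation(self):
        with pytest.raises(ValueError, match="dEJ"):
            SimulationParams(exon_count_range=(1, 1), target_features=("dej",))


class TestAnnotation:
    def test_no_planted_features(self):
        params = SimulationParams(n_genes=20, n_targets=5, target_features=(), n_switch_genes=0, n_factor_genes=0, seed=1)
        _, _, truth = simulate_annotation(params)
        assert all(len(s) == 0 for s in truth.frame["planted_features"])

    def test_truth_covers_every_gene_once(self, default_annotation):
        params, models, _, truth = default_annotation
        assert len(truth.genes) == params.n_genes
        assert truth.genes.is_unique
        model_genes = {m.gene_id for m in models}
        assert model_genes == set(truth.genes)

    def test_planted_switch_refers_to_existing_isoform(self, default_annotation):
        _, models, _, truth = default_annotation
        ids = {m.transcript_id for m in models}
        for iso in truth.frame["planted_switch"].dropna():
            assert iso in ids

    def test_planted_dej_detected(self, default_annotation):
        _, models, _, truth = default_annotation
        by_id = {m.transcript_id: m for m in models}
        for gid, row in truth.frame.iterrows():
            if "dej" in row["planted_features"]:
                assert detect_dej(by_id[f"{gid}.t1"])[0]

    def test_every_planted_feature_recovered_and_no_incidental_calls(
        self, default_annotation
    ):
        _, models, sequences, truth = default_annotation
        gene = collapse_to_gene(annotate_transcripts(models, sequences))
        switch_genes = set(truth.frame.index[truth.frame["planted_switch"].notna()])
        for gid, row in truth.frame.iterrows():
            feats = row["planted_features"]
            flags = gene.loc[gid]
            if gid not in switch_genes:
                assert bool(flags["has_dej"]) == ("dej" in feats), gid
            assert bool(flags["has_uorf"]) == ("uorf" in feats), gid
            assert bool(flags["is_long_utr3"]) == ("long3utr" in feats), gid

    def test_multi_and_single_exon_genes_emitted(self, default_annotation):
        _, models, _, _ = default_annotation
        n_exons = {m.n_exons for m in models}
        assert 1 in n_exons and max(n_exons) >= 2

    def test_orf_is_valid_at_annotated_cds(self, default_annotation):
        _, models, sequences, _ = default_annotation
        stops = {"TAA", "TAG", "TGA"}
        for m in models:
            seq = sequences[m.transcript_id]
            assert seq[m.cds_start : m.cds_start + 3] == "ATG"
            assert seq[m.cds_end - 3 : m.cds_end] in stops
            # no premature in-frame stop
            for j in range(m.cds_start + 3, m.cds_end - 3, 3):
                assert seq[j : j + 3] not in stops

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        params = SimulationParams(n_genes=25, n_targets=5, n_switch_genes=2, n_factor_genes=3, seed=42)
        for tag in ("a", "b"):
            models, seqs, _ = simulate_annotation(params)
            write_gtf(models, tmp_path / f"{tag}.gtf")
            write_fasta(seqs, tmp_path / f"{tag}.fa")
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()


class TestCounts:
    def test_no_effect_when_factor_is_one(self):
        params = SimulationParams(n_genes=15, n_targets=5, stabilization_factor=1.0, n_switch_genes=0, n_factor_genes=0, seed=2)
        models, _, truth = simulate_annotation(params)
        means = expected_count_means(models, truth, params)
        pd.testing.assert_frame_equal(means[NULL], means[CONTROL])

    def test_planted_delta_shift_closed_form(self):
        params = SimulationParams(
            n_genes=15, n_targets=5, stabilization_factor=0.5,
            n_switch_genes=0, n_factor_genes=0, seed=2,
        )
        models, _, truth = simulate_annotation(params)
        means = expected_count_means(models, truth, params)
        planted = truth.frame["is_planted_target"]
        ratio = np.log2(means[NULL]["exonic"] / means[NULL]["intronic"]) - np.log2(
            means[CONTROL]["exonic"] / means[CONTROL]["intronic"]
        )
        assert np.allclose(ratio[planted], 1.0)
        assert np.allclose(ratio[~planted].fillna(0.0), 0.0)

    def test_feedback_cancels_steady_state(self):
        params = SimulationParams(
            n_genes=15, n_targets=5, feedback_fraction=1.0, stabilization_factor=0.5,
            n_switch_genes=0, n_factor_genes=0, seed=2,
        )
        models, _, truth = simulate_annotation(params)
        means = expected_count_means(models, truth, params)
        fb = truth.frame["has_feedback"]
        assert fb.sum() == 5
        assert np.allclose(
            means[NULL].loc[fb, "exonic"], means[CONTROL].loc[fb, "exonic"]
        )
        assert np.allclose(
            means[NULL].loc[fb, "intronic"], 0.5 * means[CONTROL].loc[fb, "intronic"]
        )

    def test_intronless_genes_zero_counts(self):
        params = SimulationParams(
            n_genes=40, n_targets=0, n_factor_genes=0, n_switch_genes=0,
            exon_count_range=(1, 1), isoforms_per_gene=(1, 1), seed=3,
        )
        models, _, truth = simulate_annotation(params)
        tables = simulate_counts(models, truth, params)
        assert (tables.intronic.values == 0).all()
        assert (tables.gene_lengths["intronic_length"] == 0).all()

    def test_design_matches_params(self, default_annotation):
        params, models, _, truth = default_annotation
        tables = simulate_counts(models, truth, params)
        assert (tables.samples == NULL).sum() == params.n_null
        assert (tables.samples == CONTROL).sum() == params.n_control

    def test_nb_marginals(self):
        # 10,000 control draws per gene: mean ~ mu, var ~ mu + mu^2 * disp
        params = SimulationParams(
            n_genes=12, n_targets=0, n_factor_genes=0, n_switch_genes=0,
            isoforms_per_gene=(1, 1), exon_count_range=(2, 4),
            n_null=2, n_control=10_000, depth=50_000.0, seed=4,
        )
        models, _, truth = simulate_annotation(params)
        tables = simulate_counts(models, truth, params)
        mu = expected_count_means(models, truth, params)[CONTROL]["exonic"]
        ctrl = tables.exonic[[c for c in tables.exonic if c.startswith("ctrl")]]
        rel_mean = ctrl.mean(axis=1) / mu - 1
        assert (rel_mean.abs() < 0.05).all()
        expected_var = mu + params.dispersion * mu**2
        rel_var = ctrl.var(axis=1) / expected_var - 1
        assert (rel_var.abs() < 0.12).all()

    def test_determinism(self, default_annotation):
        params, models, _, truth = default_annotation
        t1 = simulate_counts(models, truth, params)
        t2 = simulate_counts(models, truth, params)
        pd.testing.assert_frame_equal(t1.exonic, t2.exonic)
        pd.testing.assert_frame_equal(t1.intronic, t2.intronic)


class TestIsoformTpm:
    def test_planted_switch_usage(self):
        params = SimulationParams(
            n_genes=20, n_targets=0, n_switch_genes=3, n_factor_genes=0,
            isoforms_per_gene=(2, 2), seed=5,
        )
        models, _, truth = simulate_annotation(params)
        tpm, samples = simulate_isoform_tpm(models, truth, params)
        values = tpm.drop(columns="gene_id")
        cols_null = [c for c in values if samples[c] == NULL]
        cols_ctrl = [c for c in values if samples[c] == CONTROL]
        for gid, iso in truth.frame["planted_switch"].dropna().items():
            members = tpm.index[tpm["gene_id"] == gid]
            if_null = values.loc[iso, cols_null].mean() / values.loc[members, cols_null].mean(axis=1).sum()
            if_ctrl = values.loc[iso, cols_ctrl].mean() / values.loc[members, cols_ctrl].mean(axis=1).sum()
            assert if_ctrl < 0.35 and if_null > 0.45

    def test_determinism(self, default_annotation):
        params, models, _, truth = default_annotation
        a, _ = simulate_isoform_tpm(models, truth, params)
        b, _ = simulate_isoform_tpm(models, truth, params)
        pd.testing.assert_frame_equal(a, b)


class TestStageMatrix:
    def test_rejects_nonpositive_dip(self):
        with pytest.raises(ValueError):
            simulate_stage_matrix(make_truth(), dip_depth=0.0)

    def test_baseline_lfc_zero_by_construction(self):
        truth = make_truth(n_background=30, n_targets=5, n_factors=5)
        expr = simulate_stage_matrix(truth, dip_depth=1.0, cells_per_group=200, seed=7)
        cells = expr.cells
        base = expr.matrix[cells.index[cells["stage"] == "E3.5"]].mean(axis=1)
        e45 = expr.matrix[cells.index[cells["stage"] == "E4.5"]].mean(axis=1)
        lfc = np.log2(e45 / base)
        assert lfc.abs().mean() < 0.05

    def test_target_dip_epi_specific(self):
        truth = make_truth(n_background=30, n_targets=10, n_factors=5)
        expr = simulate_stage_matrix(truth, dip_depth=1.5, cells_per_group=300, seed=8)
        cells = expr.cells
        targets = truth.genes_with_class("target")

        def lfc(lineage):
            sel = (cells["stage"] == "E5.5") & (cells["lineage"] == lineage)
            baseline = (cells["stage"] == "E3.5") & (cells["lineage"] == lineage)
            m = expr.matrix.loc[targets]
            return np.log2(
                m[cells.index[sel]].mean(axis=1) / m[cells.index[baseline]].mean(axis=1)
            ).mean()

        assert lfc("EPI") == pytest.approx(-1.5, abs=0.15)
        assert lfc("TE") == pytest.approx(0.0, abs=0.15)

    def test_factor_rise_is_transient(self):
        truth = make_truth(n_background=30, n_targets=5, n_factors=10)
        expr = simulate_stage_matrix(truth, dip_depth=1.5, cells_per_group=300, seed=9)
        cells = expr.cells
        factors = truth.genes_with_class("factor")
        m = expr.matrix.loc[factors]

        def stage_mean(stage):
            return m[cells.index[cells["stage"] == stage]].mean(axis=1)

        rise = np.log2(stage_mean("E5.5") / stage_mean("E3.5")).mean()
        after = np.log2(stage_mean("E6.5") / stage_mean("E3.5")).mean()
        assert rise == pytest.approx(1.5, abs=0.15)
        assert after == pytest.approx(0.0, abs=0.15)

    def test_determinism(self):
        truth = make_truth()
        a = simulate_stage_matrix(truth, seed=3)
        b = simulate_stage_matrix(truth, seed=3)
        pd.testing.assert_frame_equal(a.matrix, b.matrix)
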