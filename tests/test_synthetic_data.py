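import json

import numpy as np
import pytest

from tfimpact.regpotential import regulatory_potential
from tfimpact.synthetic_data import (
    SimulationConfig,
    planted_assignment,
    simulate_all,
    simulate_annotation,
    simulate_categories,
    simulate_expression,
    simulate_peaks,
    write_simulation,
)

SMALL = dict(
    n_genes=120, chrom_length=6_000_000, n_tfs=3,
    n_target_genes=30, background_peaks_per_tf=300, n_categories=10,
)


class TestConfig:
    def test_rejects_bad_frac(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_targets_down=1.5)

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=0)

    def test_rejects_bad_q_range(self):
        with pytest.raises(ValueError):
            SimulationConfig(q_value_range=(0.5, 0.1))

    def test_too_many_targets(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=10, n_target_genes=11)


class TestAnnotation:
    def test_spacing_and_uniqueness(self):
        cfg = SimulationConfig(seed=1, **SMALL)
        ann = simulate_annotation(cfg)
        tss = sorted(g.tss for g in ann.genes)
        assert len(ann) == cfg.n_genes
        assert min(np.diff(tss)) >= cfg.min_spacing
        assert len(set(tss)) == cfg.n_genes

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        a1 = simulate_annotation(cfg)
        a2 = simulate_annotation(cfg)
        assert [(g.gene_id, g.tss, g.strand) for g in a1.genes] == [
            (g.gene_id, g.tss, g.strand) for g in a2.genes
        ]

    def test_different_seeds_differ(self):
        a1 = simulate_annotation(SimulationConfig(seed=1, **SMALL))
        a2 = simulate_annotation(SimulationConfig(seed=2, **SMALL))
        assert [g.tss for g in a1.genes] != [g.tss for g in a2.genes]

    def test_infeasible_spacing_rejected(self):
        with pytest.raises(ValueError):
            simulate_annotation(SimulationConfig(n_genes=1000, chrom_length=1_000_000))


class TestPeaks:
    def test_planted_targets_covered(self):
        cfg = SimulationConfig(seed=11, proximity_sd=200.0, **SMALL)
        ann = simulate_annotation(cfg)
        truth = planted_assignment(cfg, ann)
        for ps in simulate_peaks(cfg, ann):
            if ps.tf_name != cfg.planted_tf:
                continue
            rp = regulatory_potential(ps, ann, 1000)
            for gid in truth.target_genes:
                assert rp.site_counts[gid] >= 1, (ps.replicate, gid)

    def test_background_near_tss_poisson_expectation(self):
        cfg = SimulationConfig(seed=3, **SMALL)
        ann = simulate_annotation(cfg)
        D = 1000
        bg = next(
            ps for ps in simulate_peaks(cfg, ann) if ps.tf_name != cfg.planted_tf
        )
        rp = regulatory_potential(bg, ann, D)
        observed = sum(rp.site_counts.values())
        lam = cfg.background_peaks_per_tf * (2 * D * cfg.n_genes / cfg.chrom_length)
        assert abs(observed - lam) <= 3 * np.sqrt(lam) + 1

    def test_no_background_gives_planted_only(self):
        cfg = SimulationConfig(seed=2, **{**SMALL, "background_peaks_per_tf": 0})
        ann = simulate_annotation(cfg)
        peaksets = simulate_peaks(cfg, ann)
        for ps in peaksets:
            if ps.tf_name == cfg.planted_tf:
                assert len(ps) == cfg.n_target_genes
            else:
                assert len(ps) == 0

    def test_two_replicates_per_tf(self):
        cfg = SimulationConfig(seed=2, **SMALL)
        ann = simulate_annotation(cfg)
        peaksets = simulate_peaks(cfg, ann)
        assert len(peaksets) == 2 * cfg.n_tfs
        reps = {(ps.tf_name, ps.replicate) for ps in peaksets}
        assert len(reps) == 2 * cfg.n_tfs

    def test_planted_q_pins_q_values(self):
        cfg = SimulationConfig(
            seed=2, planted_q=1e-12, **{**SMALL, "background_peaks_per_tf": 0}
        )
        ann = simulate_annotation(cfg)
        for ps in simulate_peaks(cfg, ann):
            if ps.tf_name == cfg.planted_tf:
                assert all(p.q_value == 1e-12 for p in ps.peaks)


class TestExpression:
    def test_noise_free_limit_recovers_effects(self):
        cfg = SimulationConfig(seed=4, noise_sd=1e-12, **SMALL)
        ann = simulate_annotation(cfg)
        truth = planted_assignment(cfg, ann)
        m = simulate_expression(cfg, ann)
        fc = m.group_columns("treatment").mean(axis=1) - m.group_columns("control").mean(axis=1)
        fc_by_gene = dict(zip(m.gene_ids, fc))
        for g in truth.down_targets:
            assert fc_by_gene[g] == pytest.approx(-cfg.effect_size, abs=1e-9)
        for g in truth.up_genes:
            assert fc_by_gene[g] == pytest.approx(+cfg.effect_size, abs=1e-9)
        unplanted = set(m.gene_ids) - set(truth.down_targets) - set(truth.up_genes)
        for g in list(unplanted)[:10]:
            assert fc_by_gene[g] == pytest.approx(0.0, abs=1e-9)

    def test_design_dimensions(self):
        cfg = SimulationConfig(seed=4, **SMALL)
        ann = simulate_annotation(cfg)
        m = simulate_expression(cfg, ann)
        assert m.values.shape == (cfg.n_genes, cfg.n_control + cfg.n_treatment)
        n_ctrl = sum(1 for s in m.sample_ids if m.group_labels[s] == "control")
        assert n_ctrl == cfg.n_control

    def test_null_effect_flags_few_genes(self):
        from tfimpact.diffexpr import de_gene_sets, differential_expression

        cfg = SimulationConfig(seed=8, effect_size=0.0, **SMALL)
        ann = simulate_annotation(cfg)
        m = simulate_expression(cfg, ann)
        up, down = de_gene_sets(differential_expression(m, alpha=0.01), alpha=0.01)
        assert (len(up) + len(down)) / cfg.n_genes <= 0.03


class TestCategories:
    def test_planted_overlap(self):
        cfg = SimulationConfig(seed=9, **SMALL)
        ann = simulate_annotation(cfg)
        truth = planted_assignment(cfg, ann)
        cats = simulate_categories(cfg, ann)
        planted = next(c for c in cats if c.category_id == truth.planted_category_id)
        n_core = len(planted.genes & set(truth.down_targets))
        expected = round(cfg.planted_category_overlap * len(truth.down_targets))
        assert n_core == expected

    def test_sizes_in_range(self):
        cfg = SimulationConfig(seed=9, **SMALL)
        ann = simulate_annotation(cfg)
        lo, hi = cfg.category_size_range
        for c in simulate_categories(cfg, ann):
            if c.category_id.startswith("cat0") or c.category_id.startswith("cat"):
                assert len(c.genes) <= max(hi, cfg.n_genes)

    def test_zero_overlap_category_is_null(self):
        cfg = SimulationConfig(seed=9, planted_category_overlap=0.0, **SMALL)
        ann = simulate_annotation(cfg)
        truth = planted_assignment(cfg, ann)
        cats = simulate_categories(cfg, ann)
        planted = next(c for c in cats if c.category_id == truth.planted_category_id)
        assert not (planted.genes & set(truth.down_targets))


class TestDeterminism:
    def test_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=13, **SMALL)
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        write_simulation(simulate_all(cfg), str(d1))
        write_simulation(simulate_all(cfg), str(d2))
        files1 = sorted(p.name for p in d1.iterdir())
        assert files1 == sorted(p.name for p in d2.iterdir())
        for name in files1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_truth_json_contents(self, tmp_path):
        cfg = SimulationConfig(seed=13, **SMALL)
        data = simulate_all(cfg)
        paths = write_simulation(data, str(tmp_path / "out"))
        truth = json.loads(open(paths["truth"]).read())
        assert truth["planted_tf"] == cfg.planted_tf
        assert len(truth["target_genes"]) == cfg.n_target_genes
        assert set(truth["down_targets"]) <= set(truth["target_genes"])
        assert not (set(truth["up_genes"]) & set(truth["target_genes"]))
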