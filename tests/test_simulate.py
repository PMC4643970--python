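"""Generator invariants: planted means, mixture fractions, determinism."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pantcl
from pantcl.preprocess import collapse_probes
from pantcl.simulate import SimulationConfig, simulate_dataset, simulate_ihc_table


def _noise_free_config(**overrides):
    base = dict(
        n_healthy_cd4=4,
        n_healthy_cd8=4,
        n_per_subtype={"AITL": 5, "HSTL": 3},
        n_genes=30,
        noise_log2_sd=0.0,
        planted_signature={"THY1": {"AITL": 13.65}, "CD3G": {"AITL": -3.01, "HSTL": -2.02}},
        cav1_anchor="CAV1",
        cav1_high_prob={"AITL": 1.0, "HSTL": 1.0},
        cav1_high_log2_shift=float(np.log2(16.33)),
        n_tme_genes=0,
        panel_size=10,
        seed=3,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def _group_means(dataset, gene):
    collapsed = collapse_probes(dataset.expression, dataset.probe_map)
    sig = collapsed.matrix.loc[gene]
    ann = dataset.annotations
    healthy = sig[ann["class"] == "healthy"]
    return healthy, sig, ann


class TestPlantedMeans:
    def test_noise_free_fold_change_exact(self):
        """At zero noise the subtype/healthy mean ratio equals the planted FC exactly."""
        ds = simulate_dataset(_noise_free_config(cav1_anchor="NOT_PRESENT"))
        healthy, sig, ann = _group_means(ds, "THY1")
        aitl = sig[ann["subtype"] == "AITL"]
        assert np.allclose(aitl.mean() / healthy.mean(), 13.65)
        healthy, sig, ann = _group_means(ds, "CD3G")
        hstl = sig[ann["subtype"] == "HSTL"]
        assert np.allclose(healthy.mean() / hstl.mean(), 2.02)

    def test_anchor_mixture_mean_with_certain_high(self):
        """With High probability 1 the anchor's malignant mean is baseline * 2^shift."""
        ds = simulate_dataset(_noise_free_config())
        healthy, sig, ann = _group_means(ds, "CAV1")
        malignant = sig[ann["class"] == "malignant"]
        assert np.allclose(malignant.mean() / healthy.mean(), 16.33)

    def test_null_configuration_has_no_truth(self):
        """Unit fold-changes and zero High probability plant nothing."""
        cfg = _noise_free_config(
            planted_signature={"THY1": {"AITL": 1.0}},
            cav1_high_prob={"AITL": 0.0, "HSTL": 0.0},
        )
        ds = simulate_dataset(cfg)
        assert ds.truth.planted_directions == {}
        assert not any(ds.truth.cav1_high.values())


class TestStructure:
    def test_shapes_positivity_and_probe_truth(self):
        ds = simulate_dataset(SimulationConfig(n_genes=120, panel_size=40, seed=5))
        assert (ds.expression.to_numpy() > 0).all()
        assert ds.expression.shape[1] == 239
        assert set(ds.probe_map.index) == set(ds.expression.index)
        # max-offset probe is the maximal-mean probe at the default noise level
        collapsed = collapse_probes(ds.expression, ds.probe_map)
        agree = sum(
            collapsed.chosen_probe[g] == p for g, p in ds.truth.chosen_probe.items()
        )
        assert agree >= 0.99 * len(ds.truth.chosen_probe)

    def test_high_count_within_central_binomial_interval(self):
        """AITL High draws behave as Binomial(43, 0.77) (central 99% interval)."""
        ds = simulate_dataset(SimulationConfig(seed=7))
        ann = ds.annotations
        high = pd.Series(ds.truth.cav1_high)
        aitl = high[ann.loc[high.index, "subtype"] == "AITL"]
        lo, hi = stats.binom.ppf([0.005, 0.995], 43, 0.77)
        assert lo <= aitl.sum() <= hi

    def test_determinism_and_seed_sensitivity(self):
        cfg = SimulationConfig(n_genes=80, panel_size=30, seed=11)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a.expression.to_csv() == b.expression.to_csv()
        assert a.truth.to_json() == b.truth.to_json()
        c = simulate_dataset(SimulationConfig(n_genes=80, panel_size=30, seed=12))
        assert a.expression.to_csv() != c.expression.to_csv()

    def test_tme_coupling_converges_at_large_n(self):
        """Empirical gene-anchor correlation approaches the target at n = 1000."""
        cfg = SimulationConfig(
            n_per_subtype={"AITL": 1000},
            cav1_high_prob={"AITL": 0.77},
            n_genes=100,
            n_tme_genes=10,
            panel_size=40,
            seed=21,
        )
        ds = simulate_dataset(cfg)
        collapsed = collapse_probes(ds.expression, ds.probe_map)
        ann = ds.annotations
        mal = ann.index[ann["class"] == "malignant"]
        anchor = np.log2(collapsed.matrix.loc["CAV1", mal])
        for gene, target in ds.truth.tme_coupling.items():
            r = np.corrcoef(np.log2(collapsed.matrix.loc[gene, mal]), anchor)[0, 1]
            assert abs(r - target) < 0.1, (gene, r, target)

    @pytest.mark.parametrize(
        "overrides",
        [
            {"n_per_subtype": {"AITL": 0}},
            {"planted_signature": {f"g{i}": {"AITL": 2.0} for i in range(50)}, "n_genes": 30},
            {"probes_per_gene_range": (0, 2)},
            {"cav1_high_prob": {"AITL": 1.5}},
            {"planted_signature": {"THY1": {"AITL": 0.5}}},
        ],
    )
    def test_invalid_configs_rejected(self, overrides):
        cfg = SimulationConfig(**{"n_genes": 60, "panel_size": 30, **overrides})
        with pytest.raises(ValueError):
            pantcl.simulate_dataset(cfg)


class TestIHCSimulation:
    def test_marginals_recovered_exactly(self):
        table = simulate_ihc_table({("AITL", "BCL10"): (7, 8)}, seed=1, cores_per_patient=2)
        summary = pantcl.summarize_staining(table)
        assert summary.per_subtype.loc[("AITL", "BCL10"), "n_positive"] == 7
        assert summary.per_subtype.loc[("AITL", "BCL10"), "n_patients"] == 8
        assert summary.pct("AITL", "BCL10") == 88

    def test_all_negative_and_all_positive(self):
        neg = simulate_ihc_table({("X", "M"): (0, 5)}, seed=0)
        assert len(neg) == 5 and (neg["lymphoid_call"] == "negative").all()
        pos = simulate_ihc_table({("X", "M"): (5, 5)}, seed=0)
        assert len(pos) == 5 and pos["lymphoid_call"].isin(["positive", "light"]).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            simulate_ihc_table({("X", "M"): (-1, 5)})
        with pytest.raises(ValueError):
            simulate_ihc_table({("X", "M"): (6, 5)})
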