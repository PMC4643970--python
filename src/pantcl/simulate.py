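"""Synthetic cohort generator with planted, recoverable structure.

Emulates the shape of a pooled microarray study of mature T-cell lymphomas:
52 healthy CD4+/CD8+ T-cell controls and 187 malignant biopsies across five
subtypes (AITL, ALCL, ATLL, HSTL, PTCL-NOS), probe-level MAS5-like signal with
multiple probes per gene, a planted 21-gene pan-subtype signature with known
signed fold-changes, a bimodal CAV1 anchor gene (High/Low mixture with
per-subtype High probabilities), and a block of genes whose expression is
linearly coupled to CAV1 within the malignant samples.

The expression model is log2-normal:

    log2 signal = gene baseline + probe offset + sample effect + N(0, noise)

and the emitted matrix is ``2**log2`` so values are strictly positive and
planted fold-changes act multiplicatively, as for MAS5-normalized data. Probe
offsets are drawn so that exactly one probe per gene is maximal in average
intensity, making probe collapsing truth-checkable. Healthy CD4 and CD8 cells
share generating means (the analysis pools them as controls), and CAV1-Low
malignant samples draw from the healthy CAV1 distribution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io

SUBTYPES = ("AITL", "ALCL", "ATLL", "HSTL", "PTCL-NOS")

#: Planted pan-subtype signature: signed linear fold-changes per subtype
#: (positive = up in the malignancy, negative magnitude = down), 6 up-regulated
#: and 15 down-regulated genes. Keys follow the field's gene symbols.
DEFAULT_PLANTED_SIGNATURE: dict[str, dict[str, float]] = {
    "CAV1": {"AITL": 16.33, "ALCL": 12.52, "ATLL": 38.17, "HSTL": 34.41, "PTCL-NOS": 16.33},
    "CCNB2": {"AITL": 7.55, "ALCL": 8.93, "ATLL": 13.99, "HSTL": 9.65, "PTCL-NOS": 7.55},
    "THY1": {"AITL": 13.65, "ALCL": 12.98, "ATLL": 9.46, "HSTL": 2.46, "PTCL-NOS": 13.65},
    "TNFRSF21": {"AITL": 6.38, "ALCL": 6.27, "ATLL": 5.34, "HSTL": 9.30, "PTCL-NOS": 6.38},
    "ENAH": {"AITL": 5.62, "ALCL": 5.36, "ATLL": 2.52, "HSTL": 22.63, "PTCL-NOS": 5.62},
    "PSEN2": {"AITL": 2.94, "ALCL": 4.77, "ATLL": 2.26, "HSTL": 3.39, "PTCL-NOS": 2.94},
    "CD3G": {"AITL": -3.01, "ALCL": -6.81, "ATLL": -1.65, "HSTL": -2.02, "PTCL-NOS": -3.00},
    "TNFRSF14": {"AITL": -1.49, "ALCL": -1.58, "ATLL": -1.69, "HSTL": -1.99, "PTCL-NOS": -1.49},
    "RICTOR": {"AITL": -2.42, "ALCL": -4.36, "ATLL": -1.75, "HSTL": -2.25, "PTCL-NOS": -2.42},
    "LAT": {"AITL": -2.91, "ALCL": -3.61, "ATLL": -1.92, "HSTL": -3.76, "PTCL-NOS": -2.91},
    "CD5": {"AITL": -4.12, "ALCL": -6.55, "ATLL": -2.10, "HSTL": -17.27, "PTCL-NOS": -4.11},
    "IL23A": {"AITL": -3.26, "ALCL": -3.50, "ATLL": -2.23, "HSTL": -4.51, "PTCL-NOS": -3.26},
    "ITK": {"AITL": -3.67, "ALCL": -10.78, "ATLL": -2.36, "HSTL": -2.70, "PTCL-NOS": -3.67},
    "STAT5A": {"AITL": -2.14, "ALCL": -2.11, "ATLL": -2.50, "HSTL": -2.63, "PTCL-NOS": -2.14},
    "TSC22D3": {"AITL": -5.66, "ALCL": -6.63, "ATLL": -2.56, "HSTL": -4.07, "PTCL-NOS": -5.66},
    "UBASH3A": {"AITL": -2.43, "ALCL": -4.27, "ATLL": -2.86, "HSTL": -6.97, "PTCL-NOS": -2.43},
    "PRKCQ": {"AITL": -2.98, "ALCL": -8.26, "ATLL": -3.58, "HSTL": -2.92, "PTCL-NOS": -2.98},
    "FOXP1": {"AITL": -4.90, "ALCL": -3.96, "ATLL": -3.69, "HSTL": -3.40, "PTCL-NOS": -4.90},
    "PAG1": {"AITL": -3.81, "ALCL": -2.32, "ATLL": -4.30, "HSTL": -3.69, "PTCL-NOS": -3.81},
    "BCL10": {"AITL": -4.96, "ALCL": -7.82, "ATLL": -6.54, "HSTL": -7.15, "PTCL-NOS": -4.96},
    "PDE4B": {"AITL": -4.21, "ALCL": -3.55, "ATLL": -7.44, "HSTL": -3.42, "PTCL-NOS": -4.21},
}

#: Per-subtype probability that a malignant sample is CAV1-High.
DEFAULT_CAV1_HIGH_PROB: dict[str, float] = {
    "AITL": 0.77,
    "ALCL": 0.47,
    "ATLL": 0.85,
    "HSTL": 0.75,
    "PTCL-NOS": 0.69,
}

DEFAULT_N_PER_SUBTYPE: dict[str, int] = {
    "AITL": 43,
    "ALCL": 45,
    "ATLL": 13,
    "HSTL": 8,
    "PTCL-NOS": 78,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of the synthetic cohort.

    Healthy sample counts default to the pooled-control composition of the
    emulated study (34 CD4 + 18 CD8 = 52); subtype counts to the 187-sample
    malignant cohort. ``noise_log2_sd`` is the within-group SD on the log2
    scale (0.5, a mid-range microarray value; the emulated study reports no
    within-group variances). ``cav1_high_log2_shift`` is the log2 separation
    of the CAV1-High mixture component from the healthy baseline (4.0, a
    16-fold shift on the scale of the planted CAV1 fold-changes).
    """

    n_healthy_cd4: int = 34
    n_healthy_cd8: int = 18
    n_per_subtype: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_SUBTYPE))
    n_genes: int = 2000
    probes_per_gene_range: tuple[int, int] = (1, 3)
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 0.5
    planted_signature: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(m) for g, m in DEFAULT_PLANTED_SIGNATURE.items()}
    )
    cav1_anchor: str = "CAV1"
    cav1_high_prob: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CAV1_HIGH_PROB))
    cav1_high_log2_shift: float = 4.0
    n_tme_genes: int = 30
    tme_coupling_r: float = 0.6
    panel_size: int = 217
    seed: int = 0

    def validate(self) -> None:
        counts = [self.n_healthy_cd4, self.n_healthy_cd8, *self.n_per_subtype.values()]
        if any(int(c) <= 0 for c in counts):
            raise ValueError("every declared sample group needs at least one sample")
        if not self.n_per_subtype:
            raise ValueError("no malignant subtypes declared")
        lo, hi = self.probes_per_gene_range
        if lo < 1 or hi < lo:
            raise ValueError("probes_per_gene_range must satisfy 1 <= lo <= hi")
        if len(self.planted_signature) > self.n_genes:
            raise ValueError("more planted genes than n_genes")
        for gene, fcs in self.planted_signature.items():
            for subtype, fc in fcs.items():
                if abs(fc) < 1.0:
                    raise ValueError(
                        f"planted fold-change for {gene}/{subtype} has |FC| < 1 "
                        "(signed convention: down-regulation is a negative magnitude)"
                    )
        for subtype, p in self.cav1_high_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"cav1_high_prob[{subtype}] outside [0, 1]")
        if self.n_tme_genes < 0 or not -1.0 < self.tme_coupling_r < 1.0:
            raise ValueError("invalid TME coupling parameters")
        if self.panel_size < len(self.planted_signature):
            raise ValueError("panel smaller than the planted signature")
        if self.n_genes < len(self.planted_signature) + self.n_tme_genes:
            raise ValueError("n_genes too small for planted + TME genes")


@dataclass
class SyntheticTruth:
    """Machine-readable record of what was planted, for recovery checks."""

    planted_directions: dict[str, dict[str, int]]
    cav1_high: dict[str, bool]
    tme_coupling: dict[str, float]
    chosen_probe: dict[str, str]
    expected_high_fraction: float
    seed: int

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulatedDataset:
    expression: pd.DataFrame
    probe_map: pd.Series
    annotations: pd.DataFrame
    truth: SyntheticTruth
    gene_sets: dict[str, list[str]]


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_healthy_cd4):
        rows.append((f"H_CD4_{i + 1:03d}", io.CLASS_HEALTHY, "CD4"))
    for i in range(config.n_healthy_cd8):
        rows.append((f"H_CD8_{i + 1:03d}", io.CLASS_HEALTHY, "CD8"))
    for subtype, n in config.n_per_subtype.items():
        tag = subtype.replace("-", "")
        for i in range(int(n)):
            rows.append((f"{tag}_{i + 1:03d}", io.CLASS_MALIGNANT, subtype))
    table = pd.DataFrame(rows, columns=["sample_id", "class", "subtype"]).set_index("sample_id")
    if table.index.has_duplicates:
        raise ValueError("sample id collision in declared groups")
    return table


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a probe-level cohort with planted truth.

    Identical configs (including seed) produce byte-identical outputs after
    serialization. With ``noise_log2_sd = 0`` the generating group means are
    reproduced exactly: a planted gene with signed fold-change ``f`` in
    subtype ``s`` has linear-scale mean ``baseline * f`` (``f > 0``) or
    ``baseline / |f|`` (``f < 0``) there.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = _sample_table(config)
    n_samples = len(samples)
    subtype_of = samples["subtype"].to_numpy()
    is_malignant = (samples["class"] == io.CLASS_MALIGNANT).to_numpy()

    planted = list(config.planted_signature)
    # the mixture anchor participates even when it carries no planted table entry
    head = planted + ([config.cav1_anchor] if config.cav1_anchor not in planted else [])
    n_null = config.n_genes - len(head)
    if n_null < config.n_tme_genes:
        raise ValueError("n_genes too small for planted + anchor + TME genes")
    null_genes = [f"G{i + 1:05d}" for i in range(n_null)]
    tme_genes = null_genes[: config.n_tme_genes]
    genes = head + null_genes
    n_planted = len(planted)

    baselines = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    lo, hi = config.probes_per_gene_range
    probes_per_gene = rng.integers(lo, hi + 1, config.n_genes)

    # Probe offsets: one designated probe per gene sits at offset 0; the rest
    # at offsets <= -0.25 so the maximal-mean probe is unambiguous.
    probe_ids: list[str] = []
    probe_gene_idx: list[int] = []
    offsets: list[float] = []
    chosen_probe: dict[str, str] = {}
    for gi, gene in enumerate(genes):
        k = int(probes_per_gene[gi])
        top = int(rng.integers(k))
        rest = rng.uniform(-2.0, -0.25, k - 1)
        j = 0
        for pi in range(k):
            pid = f"{gene}_{pi + 1}_at"
            probe_ids.append(pid)
            probe_gene_idx.append(gi)
            if pi == top:
                offsets.append(0.0)
                chosen_probe[gene] = pid
            else:
                offsets.append(float(rest[j]))
                j += 1

    # Per-sample gene-level effects (log2 scale).
    effects = np.zeros((config.n_genes, n_samples))
    gene_index = {g: i for i, g in enumerate(genes)}
    anchor = config.cav1_anchor
    for gene, fcs in config.planted_signature.items():
        if gene == anchor:
            continue
        gi = gene_index[gene]
        for subtype, fc in fcs.items():
            delta = np.log2(abs(fc)) * (1.0 if fc > 0 else -1.0)
            effects[gi, subtype_of == subtype] = delta

    # Anchor gene: two-component mixture over malignant samples. High samples
    # get the log2 shift; Low samples stay on the healthy distribution.
    high = np.zeros(n_samples, dtype=bool)
    if anchor in gene_index:
        gi = gene_index[anchor]
        probs = np.array([config.cav1_high_prob.get(s, 0.0) for s in subtype_of])
        draws = rng.random(n_samples)
        high = is_malignant & (draws < probs)
        effects[gi, :] = np.where(high, config.cav1_high_log2_shift, 0.0)

    # Noise drawn per probe and sample.
    n_probes = len(probe_ids)
    noise = (
        rng.normal(0.0, config.noise_log2_sd, (n_probes, n_samples))
        if config.noise_log2_sd > 0
        else np.zeros((n_probes, n_samples))
    )

    # TME genes track the anchor's realized (max-probe) log2 signal within the
    # malignant samples, with slope calibrated to the target Pearson r. Their
    # healthy-sample means are uncoupled so the healthy-vs-malignant contrasts
    # stay clean. At noise 0 the coupling degenerates (slope 0).
    tme_coupling: dict[str, float] = {}
    if tme_genes and anchor in gene_index:
        probs = np.array([config.cav1_high_prob.get(s, 0.0) for s in subtype_of])
        p_bar = float(probs[is_malignant].mean())
        shift = config.cav1_high_log2_shift
        var_d = shift**2 * p_bar * (1 - p_bar) + config.noise_log2_sd**2
        anchor_row = probe_ids.index(chosen_probe[anchor])
        anchor_log2 = (
            baselines[gene_index[anchor]]
            + effects[gene_index[anchor], :]
            + noise[anchor_row, :]
        )
        d = np.where(is_malignant, anchor_log2 - (baselines[gene_index[anchor]] + shift * p_bar), 0.0)
        r = config.tme_coupling_r
        signs = np.where(rng.random(len(tme_genes)) < 0.5, 1.0, -1.0)
        for sj, gene in zip(signs, tme_genes):
            target = float(sj * r)
            if config.noise_log2_sd > 0 and var_d > 0 and abs(target) > 0:
                slope = target * config.noise_log2_sd / (np.sqrt(var_d) * np.sqrt(1 - target**2))
            else:
                slope = 0.0
            effects[gene_index[gene], :] += slope * d
            tme_coupling[gene] = target

    gene_idx_arr = np.asarray(probe_gene_idx)
    log2m = (
        baselines[gene_idx_arr][:, None]
        + np.asarray(offsets)[:, None]
        + effects[gene_idx_arr, :]
        + noise
    )
    expression = pd.DataFrame(2.0**log2m, index=pd.Index(probe_ids, name="probe_id"), columns=samples.index)

    probe_map = pd.Series(
        [genes[i] for i in probe_gene_idx], index=pd.Index(probe_ids, name="probe_id"), name="gene_symbol"
    )

    # |FC| == 1 plants no effect, so it contributes no direction to the truth.
    planted_directions = {}
    for gene, fcs in config.planted_signature.items():
        dirs = {s: (1 if fc > 0 else -1) for s, fc in fcs.items() if abs(fc) > 1.0}
        if dirs:
            planted_directions[gene] = dirs
    probs = np.array([config.cav1_high_prob.get(s, 0.0) for s in subtype_of])
    expected_high = float(probs[is_malignant].mean()) if is_malignant.any() else 0.0
    truth = SyntheticTruth(
        planted_directions=planted_directions,
        cav1_high={sid: bool(h) for sid, h, m in zip(samples.index, high, is_malignant) if m},
        tme_coupling=tme_coupling,
        chosen_probe=chosen_probe,
        expected_high_fraction=expected_high,
        seed=config.seed,
    )

    up = sorted(g for g, fcs in config.planted_signature.items() if all(fc > 0 for fc in fcs.values()))
    down = sorted(g for g, fcs in config.planted_signature.items() if all(fc < 0 for fc in fcs.values()))
    non_tme_nulls = [g for g in null_genes if g not in tme_genes]
    panel = planted + non_tme_nulls[: config.panel_size - n_planted]
    gene_sets = {
        "TCELL_COMPARTMENT": panel,
        "PLANTED_UP": up,
        "PLANTED_DOWN": down,
        "TME_COUPLED": list(tme_genes),
    }
    if len(non_tme_nulls) > config.panel_size:
        gene_sets["RANDOM_NULL_50"] = sorted(
            rng.choice(non_tme_nulls, size=min(50, len(non_tme_nulls)), replace=False).tolist()
        )

    return SimulatedDataset(expression, probe_map, samples, truth, gene_sets)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "probe_map": outdir / "probe_map.tsv",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "truth.json",
        "gene_sets": outdir / "gene_sets.gmt",
    }
    io.write_expression(dataset.expression, paths["expression"], index_label="probe_id")
    io.write_probe_map(dataset.probe_map, paths["probe_map"])
    io.write_annotations(dataset.annotations, paths["annotations"])
    io.write_json(dataset.truth.to_json(), paths["truth"])
    io.write_gmt(dataset.gene_sets, paths["gene_sets"])
    return paths


def simulate_ihc_table(
    per_subtype_counts: dict[tuple[str, str], tuple[int, int]],
    seed: int = 0,
    cores_per_patient: int = 1,
    light_fraction: float = 0.15,
) -> pd.DataFrame:
    """Emit per-core staining calls matching the requested patient marginals exactly.

    ``per_subtype_counts`` maps (subtype, marker) to (n positive patients,
    n patients). A positive patient has at least one core scored positive (a
    fraction of positive calls are emitted as "light", which tabulation merges
    into positive); negative patients have all cores negative. Patient counts
    must agree across markers within a subtype.
    """
    rng = np.random.default_rng(seed)
    totals: dict[str, int] = {}
    for (subtype, marker), (n_pos, n_total) in per_subtype_counts.items():
        if n_pos < 0 or n_total < 0:
            raise ValueError(f"negative counts for {(subtype, marker)}")
        if n_pos > n_total:
            raise ValueError(f"n_positive > n_total for {(subtype, marker)}")
        if totals.setdefault(subtype, n_total) != n_total:
            raise ValueError(f"inconsistent patient counts for subtype {subtype}")
    records = []
    for (subtype, marker), (n_pos, n_total) in per_subtype_counts.items():
        patients = [f"{subtype.replace('-', '')}_P{i + 1:03d}" for i in range(n_total)]
        positive = set(rng.choice(n_total, size=n_pos, replace=False).tolist()) if n_pos else set()
        for pi, patient in enumerate(patients):
            pos_core = int(rng.integers(cores_per_patient)) if pi in positive else -1
            for ci in range(cores_per_patient):
                if pi in positive and (ci == pos_core or rng.random() < 0.5):
                    call = "light" if rng.random() < light_fraction else "positive"
                else:
                    call = "negative"
                stromal = "positive" if rng.random() < 0.15 else "negative"
                records.append(
                    (f"{patient}_{marker}_c{ci + 1}", patient, subtype, marker, call, stromal)
                )
    return pd.DataFrame(
        records,
        columns=["core_id", "patient_id", "subtype", "marker", "lymphoid_call", "stromal_call"],
    )
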