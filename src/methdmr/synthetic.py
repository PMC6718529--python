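"""Synthetic EPIC-like methylation cohorts with known ground truth.

The generator emulates the statistical structure a blood-methylome case/
control study assumes: a spatially clustered probe manifest (CpG islands
separated by wide gaps, so a 1,000-bp neighbourhood is meaningful), a
bimodal baseline methylation landscape shared within islands (which
induces the spatial autocorrelation region calling exploits), group-offset
DMRs injected on the natural-logit scale, linear per-year age trends,
optional group-specific age slopes (interaction effects), leukocyte-
mixture confounding driven by a reference panel and per-sample Dirichlet
proportions, logit-normal biological noise plus additive measurement
noise, and a bisulfite-pyrosequencing-style repeat-element assay.

Every draw is deterministic given the seed, and the injected truth is
exported so recovery of each downstream stage can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    BetaMatrix,
    FormatError,
    GENE_REGION_VOCAB,
    ParameterError,
    ProbeManifest,
    ReferencePanel,
    SampleSheet,
)

DEFAULT_CELLTYPES = (
    "neutrophils", "cd4_t", "cd8_t", "b_cells", "nk_cells", "monocytes",
)

#: Dirichlet concentration: typical whole-blood mean fractions x 50, giving
#: realistic between-subject variation in cell composition.
DEFAULT_DIRICHLET_ALPHA = tuple(
    np.array([0.55, 0.12, 0.08, 0.06, 0.07, 0.12]) * 50.0
)

#: Per-family (baseline mean, between-sample SD) in percentage points for
#: the repeat-element assay; baselines sit near typical whole-blood values.
REPEAT_FAMILY_DEFAULTS = {
    "ALU": (25.0, 1.0),
    "LINE1": (84.0, 1.5),
    "alpha_satellite": (88.4, 1.5),
    "rDNA_promoter": (18.0, 5.0),
}

_GENE_REGION_CHOICES = sorted(GENE_REGION_VOCAB)


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _check_range(name, rng_pair):
    lo, hi = rng_pair
    if lo > hi:
        raise ParameterError(f"{name}: min {lo} exceeds max {hi}")
    return lo, hi


# ---------------------------------------------------------------------------
# manifest / cohort
# ---------------------------------------------------------------------------

def generate_manifest(
    n_probes: int,
    n_chroms: int = 4,
    seed: int = 0,
    island_size_range: tuple[int, int] = (5, 30),
    intra_island_gap_range: tuple[int, int] = (20, 100),
    inter_island_gap_range: tuple[int, int] = (1500, 5000),
    snp_fraction: float = 0.02,
) -> ProbeManifest:
    """Generate a sorted manifest of probes grouped into CpG islands.

    Probes within an island are 20-100 bp apart by default while islands
    are 1.5-5 kb apart, so neighbourhood windows of ~1 kb never bridge
    islands.  Each island carries one synthetic gene symbol; a small
    fraction of probes is flagged as SNP-overlapping.
    """
    if n_probes < 10:
        raise ParameterError("n_probes must be >= 10")
    lo_s, hi_s = _check_range("island_size_range", island_size_range)
    lo_i, hi_i = _check_range("intra_island_gap_range", intra_island_gap_range)
    lo_o, hi_o = _check_range("inter_island_gap_range", inter_island_gap_range)
    if hi_i >= lo_o:
        raise ParameterError("intra-island gaps must be smaller than inter-island gaps")
    rng = np.random.default_rng(seed)

    sizes: list[int] = []
    total = 0
    while total < n_probes:
        s = int(rng.integers(lo_s, hi_s + 1))
        s = min(s, n_probes - total)
        sizes.append(s)
        total += s

    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    next_pos = {c: 10_000 for c in chrom_names}
    records = []
    probe_counter = 0
    for island_idx, size in enumerate(sizes):
        chrom = chrom_names[island_idx % n_chroms]
        pos = next_pos[chrom] + int(rng.integers(lo_o, hi_o + 1))
        gene = f"GENE{island_idx:04d}"
        for k in range(size):
            if k > 0:
                pos += int(rng.integers(lo_i, hi_i + 1))
            if size >= 3 and k == 0:
                relation = "N_Shore"
            elif size >= 3 and k == size - 1:
                relation = "S_Shore"
            else:
                relation = "Island"
            records.append({
                "probe_id": f"cg{probe_counter:07d}",
                "chrom": chrom,
                "pos": pos,
                "genes": [gene],
                "gene_region": [str(rng.choice(_GENE_REGION_CHOICES))],
                "island_relation": relation,
                "snp_overlap": bool(rng.random() < snp_fraction),
                "sex_chrom": False,
            })
            probe_counter += 1
        next_pos[chrom] = pos

    df = pd.DataFrame.from_records(records).set_index("probe_id")
    return ProbeManifest(df).sort_genomic()


def infer_islands(manifest: ProbeManifest, max_gap: int = 500) -> list[list[str]]:
    """Group sorted manifest probes into islands by breaking at gaps > max_gap."""
    df = manifest.sort_genomic().table
    islands: list[list[str]] = []
    current: list[str] = []
    prev_chrom, prev_pos = None, None
    for pid, row in df.iterrows():
        if current and (row["chrom"] != prev_chrom or row["pos"] - prev_pos > max_gap):
            islands.append(current)
            current = []
        current.append(pid)
        prev_chrom, prev_pos = row["chrom"], row["pos"]
    if current:
        islands.append(current)
    return islands


def generate_cohort(
    n_cases: int,
    n_controls: int,
    age_range: tuple[float, float] = (18, 59),
    seed: int = 0,
    matched: bool = True,
) -> SampleSheet:
    """Generate a case/control sample sheet, pairwise matched on age and sex."""
    if n_cases < 2 or n_controls < 2:
        raise ParameterError("need at least 2 samples per group")
    if matched and n_cases != n_controls:
        raise ParameterError("matched design requires n_cases == n_controls")
    lo, hi = _check_range("age_range", age_range)
    rng = np.random.default_rng(seed)
    rows = []
    if matched:
        for i in range(n_cases):
            age = int(rng.integers(int(lo), int(hi) + 1))
            sex = "F" if rng.random() < 0.5 else "M"
            pair = f"P{i:02d}"
            rows.append({"sample_id": f"CASE{i:02d}", "group": "case",
                         "age": age, "sex": sex, "pair_id": pair})
            rows.append({"sample_id": f"CTRL{i:02d}", "group": "control",
                         "age": age, "sex": sex, "pair_id": pair})
    else:
        for i in range(n_cases):
            rows.append({"sample_id": f"CASE{i:02d}", "group": "case",
                         "age": int(rng.integers(int(lo), int(hi) + 1)),
                         "sex": "F" if rng.random() < 0.5 else "M",
                         "pair_id": ""})
        for i in range(n_controls):
            rows.append({"sample_id": f"CTRL{i:02d}", "group": "control",
                         "age": int(rng.integers(int(lo), int(hi) + 1)),
                         "sex": "F" if rng.random() < 0.5 else "M",
                         "pair_id": ""})
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleSheet(df, age_range=(float(lo), float(hi)))


# ---------------------------------------------------------------------------
# baselines / reference panel / truth
# ---------------------------------------------------------------------------

#: (weight, beta range) strata of the bimodal baseline landscape: mostly
#: unmethylated islands, a methylated compartment, some intermediate.
DEFAULT_BASELINE_MIX = (
    (0.6, (0.05, 0.20)),
    (0.3, (0.70, 0.95)),
    (0.1, (0.35, 0.65)),
)


def generate_baselines(
    manifest: ProbeManifest,
    seed: int = 0,
    mix=DEFAULT_BASELINE_MIX,
) -> pd.Series:
    """Island-shared baseline methylation on the logit scale, per probe.

    The shared island-level baseline is what makes neighbouring probes
    spatially correlated, which the autocorrelation-corrected region
    caller assumes.
    """
    rng = np.random.default_rng(seed)
    weights = np.array([w for w, _ in mix], dtype=float)
    weights = weights / weights.sum()
    islands = infer_islands(manifest)
    baseline = {}
    for island in islands:
        stratum = rng.choice(len(mix), p=weights)
        lo, hi = mix[stratum][1]
        beta0 = rng.uniform(lo, hi)
        for pid in island:
            baseline[pid] = float(_logit(beta0))
    return pd.Series(baseline).reindex(manifest.sort_genomic().probe_ids)


def generate_reference_panel(
    manifest: ProbeManifest,
    n_panel_probes: int = 600,
    celltypes=DEFAULT_CELLTYPES,
    seed: int = 0,
) -> ReferencePanel:
    """Draw an idealized leukocyte reference panel on manifest probes."""
    rng = np.random.default_rng(seed)
    eligible = manifest.table.index[~manifest.table["snp_overlap"]
                                    & ~manifest.table["sex_chrom"]]
    if len(eligible) < n_panel_probes:
        raise ParameterError("not enough unflagged probes for the panel")
    probes = sorted(rng.choice(eligible, size=n_panel_probes, replace=False))
    values = rng.uniform(0.05, 0.95, size=(n_panel_probes, len(celltypes)))
    df = pd.DataFrame(values, index=probes, columns=list(celltypes))
    return ReferencePanel(df)


@dataclass
class DmrTruth:
    chrom: str
    start: int
    end: int
    probe_ids: list[str]
    delta_logit: float
    direction: int  # +1 hyper, -1 hypo


@dataclass
class SyntheticTruth:
    """Ground truth of every injected effect, the oracle for recovery tests."""

    dmrs: list[DmrTruth] = field(default_factory=list)
    age_slopes: dict[str, float] = field(default_factory=dict)       # beta/yr
    interaction_slopes: dict[str, float] = field(default_factory=dict)  # beta/yr
    celltype_probes: list[str] = field(default_factory=list)

    def dmr_probe_ids(self) -> set[str]:
        out: set[str] = set()
        for d in self.dmrs:
            out.update(d.probe_ids)
        return out

    def save(self, path) -> None:
        payload = {
            "dmrs": [
                {"chrom": d.chrom, "start": d.start, "end": d.end,
                 "probe_ids": d.probe_ids, "delta_logit": d.delta_logit,
                 "direction": d.direction}
                for d in self.dmrs
            ],
            "age_slopes": self.age_slopes,
            "interaction_slopes": self.interaction_slopes,
            "celltype_probes": self.celltype_probes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            dmrs=[DmrTruth(**d) for d in payload["dmrs"]],
            age_slopes=payload["age_slopes"],
            interaction_slopes=payload["interaction_slopes"],
            celltype_probes=payload["celltype_probes"],
        )


def generate_truth(
    manifest: ProbeManifest,
    n_dmrs: int = 40,
    seed: int = 0,
    delta_logit_range: tuple[float, float] = (0.4, 0.8),
    delta_beta_range: tuple[float, float] | None = None,
    baselines: pd.Series | None = None,
    hyper_fraction: float = 0.78,
    n_age_probes: int = 0,
    age_slope_range: tuple[float, float] = (0.0005, 0.002),
    n_interaction_probes: int = 0,
    interaction_slope_range: tuple[float, float] = (0.002, 0.006),
    min_dmr_probes: int = 2,
    exclude_probes=(),
) -> SyntheticTruth:
    """Choose whole islands as DMRs and disjoint probes for age/interaction.

    DMR effects are stored on the natural-logit scale.  When
    ``delta_beta_range`` (with ``baselines``) is given, each region's
    logit offset is derived so the noiseless group difference on the beta
    scale hits a target drawn from that range at the island's baseline.
    Directions are +1 (hypermethylated in cases) with probability
    ``hyper_fraction``.
    """
    if not 0.0 <= hyper_fraction <= 1.0:
        raise ParameterError("hyper_fraction must lie in [0, 1]")
    if delta_beta_range is not None and baselines is None:
        raise ParameterError("delta_beta_range requires baselines")
    rng = np.random.default_rng(seed)
    flagged = set(manifest.table.index[manifest.table["snp_overlap"]
                                       | manifest.table["sex_chrom"]])
    excluded = flagged | set(exclude_probes)
    df = manifest.sort_genomic().table

    islands = infer_islands(manifest)
    clean_islands = [
        [p for p in isl if p not in excluded] for isl in islands
    ]
    eligible = [isl for isl in clean_islands if len(isl) >= min_dmr_probes]
    if n_dmrs > len(eligible):
        raise ParameterError(
            f"requested {n_dmrs} DMRs but only {len(eligible)} eligible islands"
        )
    chosen_idx = rng.choice(len(eligible), size=n_dmrs, replace=False) if n_dmrs else []

    dmrs: list[DmrTruth] = []
    for idx in chosen_idx:
        probes = eligible[idx]
        direction = 1 if rng.random() < hyper_fraction else -1
        if delta_beta_range is not None:
            target = rng.uniform(*delta_beta_range)
            base_beta = float(_invlogit(baselines.loc[probes[0]]))
            achieved = np.clip(base_beta + direction * target, 0.02, 0.98)
            delta = float(_logit(achieved) - _logit(base_beta))
        else:
            delta = direction * rng.uniform(*delta_logit_range)
        positions = df.loc[probes, "pos"]
        dmrs.append(DmrTruth(
            chrom=str(df.loc[probes[0], "chrom"]),
            start=int(positions.min()),
            end=int(positions.max()),
            probe_ids=list(probes),
            delta_logit=delta,
            direction=direction,
        ))

    used = excluded | {p for d in dmrs for p in d.probe_ids}
    free = [p for p in df.index if p not in used]
    if n_age_probes + n_interaction_probes > len(free):
        raise ParameterError("not enough free probes for age/interaction effects")
    picked = list(rng.choice(free, size=n_age_probes + n_interaction_probes,
                             replace=False)) if (n_age_probes + n_interaction_probes) else []
    age_probes = picked[:n_age_probes]
    inter_probes = picked[n_age_probes:]
    age_slopes = {p: float(rng.uniform(*age_slope_range)) for p in age_probes}
    inter_slopes = {p: float(rng.uniform(*interaction_slope_range)) for p in inter_probes}
    return SyntheticTruth(dmrs=dmrs, age_slopes=age_slopes,
                          interaction_slopes=inter_slopes)


# ---------------------------------------------------------------------------
# beta simulation
# ---------------------------------------------------------------------------

def simulate_betas(
    manifest: ProbeManifest,
    sheet: SampleSheet,
    truth: SyntheticTruth | None = None,
    panel: ReferencePanel | None = None,
    baselines: pd.Series | None = None,
    noise_sd_logit: float = 0.15,
    measurement_sd_beta: float = 0.01,
    dirichlet_alpha=DEFAULT_DIRICHLET_ALPHA,
    seed: int = 0,
    epsilon: float = 1e-6,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Simulate the beta matrix and return it with true cell proportions.

    For probe p and sample s the noiseless methylation fraction is
    ``invlogit(baseline_p + case_s * delta_p) + slope_p * age_s
    + case_s * islope_p * age_s``; panel probes instead take the mixture
    of reference columns weighted by the sample's Dirichlet-drawn cell
    proportions.  Biological noise is added on the logit scale
    (``noise_sd_logit``), measurement noise on the beta scale, and the
    result is clipped to [eps, 1-eps].  Age and interaction slopes act on
    the beta scale so their per-year unit matches how array studies
    report them (fraction, i.e. percentage points / 100, per year).
    """
    truth = truth or SyntheticTruth()
    rng = np.random.default_rng(seed)
    manifest = manifest.sort_genomic()
    probe_ids = manifest.probe_ids
    if baselines is None:
        baselines = generate_baselines(manifest, seed=int(rng.integers(2**31)))
    baselines = baselines.reindex(probe_ids)
    if baselines.isna().any():
        raise FormatError("baselines missing for some manifest probes")

    n_p, n_s = len(probe_ids), len(sheet.sample_ids)
    case = sheet.is_case().astype(float)
    age = sheet.table["age"].to_numpy(dtype=float)

    pidx = {p: i for i, p in enumerate(probe_ids)}
    delta = np.zeros(n_p)
    for d in truth.dmrs:
        for p in d.probe_ids:
            delta[pidx[p]] = d.delta_logit
    slope = np.zeros(n_p)
    for p, s in truth.age_slopes.items():
        slope[pidx[p]] = s
    islope = np.zeros(n_p)
    for p, s in truth.interaction_slopes.items():
        islope[pidx[p]] = s

    mu = baselines.to_numpy()[:, None] + delta[:, None] * case[None, :]

    props = None
    if panel is not None:
        missing = [p for p in panel.probe_ids if p not in pidx]
        if missing:
            raise FormatError(f"panel probes missing from manifest: {missing[:10]}")
        alpha = np.asarray(dirichlet_alpha, dtype=float)
        if len(alpha) != len(panel.celltype_names):
            raise ParameterError("dirichlet_alpha length must match cell types")
        w = rng.dirichlet(alpha, size=n_s)                       # samples x types
        mix = panel.mean_betas.to_numpy() @ w.T                  # probes x samples
        rows = [pidx[p] for p in panel.probe_ids]
        mu[rows, :] = _logit(np.clip(mix, epsilon, 1 - epsilon))
        props = pd.DataFrame(w, index=sheet.sample_ids,
                             columns=panel.celltype_names)
        truth.celltype_probes = list(panel.probe_ids)

    if noise_sd_logit > 0:
        mu = mu + rng.normal(0.0, noise_sd_logit, size=(n_p, n_s))
    beta = _invlogit(mu)
    beta = beta + slope[:, None] * age[None, :] \
        + islope[:, None] * (age * case)[None, :]
    if measurement_sd_beta > 0:
        beta = beta + rng.normal(0.0, measurement_sd_beta, size=(n_p, n_s))
    beta = np.clip(beta, epsilon, 1 - epsilon)
    matrix = BetaMatrix(pd.DataFrame(beta, index=probe_ids,
                                     columns=sheet.sample_ids))
    if props is None:
        props = pd.DataFrame(index=sheet.sample_ids)
    return matrix, props


# ---------------------------------------------------------------------------
# repeat-element assay
# ---------------------------------------------------------------------------

def generate_repeat_assay(
    sheet: SampleSheet,
    families=tuple(REPEAT_FAMILY_DEFAULTS),
    group_effect=0.0,
    seed: int = 0,
    family_params: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-sample mean methylation (percentage points) per repeat family.

    ``group_effect`` (a scalar or per-family dict, percentage points) is
    added to case samples.  Returns a samples x families DataFrame with
    values in [0, 100].
    """
    params = dict(REPEAT_FAMILY_DEFAULTS)
    if family_params:
        params.update(family_params)
    unknown = [f for f in families if f not in params]
    if unknown:
        raise ParameterError(f"unknown repeat families: {unknown}")
    if not isinstance(group_effect, dict):
        group_effect = {f: float(group_effect) for f in families}
    rng = np.random.default_rng(seed)
    case = sheet.is_case().astype(float)
    data = {}
    for fam in families:
        mean, sd = params[fam]
        vals = mean + group_effect.get(fam, 0.0) * case \
            + rng.normal(0.0, sd, size=len(case))
        data[fam] = np.clip(vals, 0.0, 100.0)
    return pd.DataFrame(data, index=sheet.sample_ids)
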