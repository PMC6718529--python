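"""Autocorrelation-corrected DMR calling from per-probe p-values.

Nearby CpGs on methylation arrays carry correlated signals, so a run of
moderately small p-values in a tight genomic window is stronger evidence
than the individual sites suggest — but combining them naively overstates
it.  The region caller proceeds in four stages:

1. *Autocorrelation estimation*: Pearson correlation of probit-
   transformed p-values as a function of genomic lag, in base-pair bins
   up to a window ``dist`` (default 1,000 bp).
2. *Per-probe smoothing*: each probe's p-value is replaced by a
   Stouffer-Liptak combination of all p-values within ``dist``, using
   the lag-binned autocorrelation as the pairwise correlation of the
   normal quantiles (the Stouffer-Liptak-Kechris, SLK, correction).
3. *Peak finding*: regions seed at probes with SLK p below ``seed_p``
   (default 0.05) and extend while the next probe also falls below the
   threshold and lies within ``dist`` of the previous member.
4. *Region significance*: a Stouffer-Liptak combination of the region's
   original (pre-smoothing) p-values, followed by a Sidak correction for
   the number of possible regions of the same size in the analyzed
   territory.

Regions are then annotated with mean methylation, the mean and largest
case-minus-control beta difference, direction (hyper/hypo), and the
manifest's gene and island annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import (
    BetaMatrix,
    FormatError,
    ParameterError,
    ProbeManifest,
    SampleSheet,
)

_P_CLAMP = 1e-15


@dataclass
class ACFEstimate:
    """Lag-binned autocorrelation of probit-transformed p-values.

    ``bin_edges`` are base-pair boundaries 0, w, 2w, ..., dist; bin k
    covers lags in (edges[k], edges[k+1]].  Lag 0 has correlation 1 by
    definition; estimated correlations are clipped to [0, 1].
    """

    bin_edges: np.ndarray
    correlations: np.ndarray
    n_pairs: np.ndarray

    def lookup(self, distances: np.ndarray) -> np.ndarray:
        """Correlation for each genomic lag; 1 at lag 0, 0 beyond the window."""
        d = np.asarray(distances, dtype=float)
        out = np.zeros_like(d)
        out[d == 0] = 1.0
        dist = self.bin_edges[-1]
        width = self.bin_edges[1] - self.bin_edges[0]
        inside = (d > 0) & (d <= dist)
        idx = np.minimum(
            np.ceil(d[inside] / width).astype(int) - 1, len(self.correlations) - 1
        )
        out[inside] = self.correlations[idx]
        return out


@dataclass
class DMR:
    """A called differentially methylated region (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    probe_ids: list[str]
    p_region: float
    p_sidak: float
    mean_beta: float = np.nan
    mean_diff: float = np.nan
    largest_diff: float = np.nan
    direction: str = ""
    genes: list[str] = field(default_factory=list)
    gene_regions: list[str] = field(default_factory=list)
    island_relations: list[str] = field(default_factory=list)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------

def probit_z(p):
    """z = Phi^-1(1 - p): larger z means smaller p."""
    p = np.clip(np.asarray(p, dtype=float), _P_CLAMP, 1.0 - _P_CLAMP)
    out = stats.norm.isf(p)
    return out if out.ndim else float(out)


def stouffer_liptak(p, pairwise_corr=None) -> float:
    """Combine p-values allowing for correlation of their normal quantiles.

    ``Z = sum(z_i) / sqrt(sum_ij sigma_ij)`` with sigma the correlation
    matrix of the quantiles (identity by default); the combined p is the
    upper normal tail of Z.  Reduces to plain Stouffer when the off-
    diagonals are zero and to the single p-value for one element.
    """
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise FormatError("NaN p-value passed to stouffer_liptak")
    m = p.size
    if pairwise_corr is None:
        sigma = np.eye(m)
    else:
        sigma = np.asarray(pairwise_corr, dtype=float)
        if sigma.shape != (m, m):
            raise ParameterError("correlation matrix shape mismatch")
        if not np.allclose(sigma, sigma.T):
            raise ParameterError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(sigma), 1.0):
            raise ParameterError("correlation matrix must have unit diagonal")
        if ((sigma < 0) | (sigma > 1)).any():
            raise ParameterError("correlation entries must lie in [0, 1]")
    z = probit_z(p)
    Z = z.sum() / np.sqrt(sigma.sum())
    return float(stats.norm.sf(Z))


def sidak_correct(p_region: float, region_len: int, total_len: int) -> float:
    """Familywise correction for the number of possible same-size regions.

    ``p_sidak = 1 - (1 - p_region)^(total_len / region_len)``, evaluated
    through log1p/expm1 for numerical stability and capped at 1.
    """
    if region_len <= 0:
        raise ParameterError("region_len must be positive")
    if total_len < region_len:
        raise ParameterError("total_len must be >= region_len")
    if p_region <= 0:
        return 0.0
    ratio = total_len / region_len
    return float(min(1.0, -np.expm1(ratio * np.log1p(-min(p_region, 1.0)))))


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------

def estimate_acf(
    p: np.ndarray,
    manifest: ProbeManifest,
    dist: int = 1000,
    bin_width: int = 50,
    min_pairs: int = 10,
) -> ACFEstimate:
    """Estimate the lag-binned autocorrelation of probit p-values.

    ``p`` must align with the genomically sorted manifest.  All
    unordered probe pairs on the same chromosome separated by at most
    ``dist`` bp contribute (symmetrized, i.e. in both orientations) to
    the Pearson correlation of their bin.  Bins with fewer than
    ``min_pairs`` pairs inherit the previous bin's value (0 for the
    first); negative estimates are clipped to 0.
    """
    df = manifest.sort_genomic().table
    p = np.asarray(p, dtype=float)
    if len(p) != len(df):
        raise ParameterError("p-value vector does not match manifest length")
    z = probit_z(p)
    n_bins = int(np.ceil(dist / bin_width))
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)

    sx = np.zeros(n_bins)
    sxx = np.zeros(n_bins)
    sxy = np.zeros(n_bins)
    npair = np.zeros(n_bins, dtype=int)

    pos = df["pos"].to_numpy()
    chrom = df["chrom"].to_numpy()
    for c in np.unique(chrom):
        mask = chrom == c
        pc, zc = pos[mask], z[mask]
        m = len(pc)
        offset = 1
        while offset < m:
            gaps = pc[offset:] - pc[:-offset]
            inside = gaps <= dist
            if not inside.any():
                break
            g = gaps[inside]
            zi = zc[:-offset][inside]
            zj = zc[offset:][inside]
            bins = np.minimum(np.ceil(np.maximum(g, 1) / bin_width).astype(int) - 1,
                              n_bins - 1)
            np.add.at(sx, bins, zi + zj)
            np.add.at(sxx, bins, zi ** 2 + zj ** 2)
            np.add.at(sxy, bins, 2.0 * zi * zj)
            np.add.at(npair, bins, 1)
            offset += 1

    correlations = np.zeros(n_bins)
    any_pairs = npair.sum() > 0
    if not any_pairs:
        import warnings
        warnings.warn("no probe pairs within the autocorrelation window; ACF set to 0")
    prev = 0.0
    for k in range(n_bins):
        if npair[k] >= min_pairs:
            n2 = 2.0 * npair[k]
            mean = sx[k] / n2
            var = sxx[k] / n2 - mean ** 2
            cov = sxy[k] / n2 - mean ** 2
            corr = cov / var if var > 0 else 0.0
            correlations[k] = float(np.clip(corr, 0.0, 1.0))
        else:
            correlations[k] = prev
        prev = correlations[k]
    return ACFEstimate(bin_edges=edges, correlations=correlations, n_pairs=npair)


# ---------------------------------------------------------------------------
# SLK smoothing, peak finding, region significance
# ---------------------------------------------------------------------------

def slk_correct(
    p: np.ndarray,
    manifest: ProbeManifest,
    acf: ACFEstimate,
    dist: int = 1000,
) -> np.ndarray:
    """Per-probe SLK-corrected p: combine all p-values within +-dist.

    Isolated probes (no neighbour in the window) keep their original p.
    """
    df = manifest.sort_genomic().table
    p = np.asarray(p, dtype=float)
    if len(p) != len(df):
        raise ParameterError("p-value vector does not match manifest length")
    pos = df["pos"].to_numpy()
    chrom = df["chrom"].to_numpy()
    out = np.empty_like(p)
    start = 0
    for c, count in zip(*np.unique(chrom, return_counts=True)):
        sl = slice(start, start + count)
        pc, ppc = pos[sl], p[sl]
        lo = np.searchsorted(pc, pc - dist, side="left")
        hi = np.searchsorted(pc, pc + dist, side="right")
        res = np.empty(count)
        for i in range(count):
            a, b = lo[i], hi[i]
            if b - a == 1:
                res[i] = ppc[i]
                continue
            window_pos = pc[a:b]
            d = np.abs(window_pos[:, None] - window_pos[None, :])
            sigma = acf.lookup(d)
            np.fill_diagonal(sigma, 1.0)
            res[i] = stouffer_liptak(ppc[a:b], sigma)
        out[sl] = res
        start += count
    return out


def find_candidate_regions(
    slk_p: np.ndarray,
    manifest: ProbeManifest,
    seed_p: float = 0.05,
    dist: int = 1000,
    min_probes: int = 2,
) -> list[dict]:
    """Scan each chromosome for runs of sub-threshold SLK p-values.

    A region seeds at a probe with SLK p < seed_p and extends to the
    next probe while that probe is also below the threshold and within
    ``dist`` of the previous member.  Runs shorter than ``min_probes``
    are dropped.  Returns dicts with chrom/start/end/probe indices into
    the sorted manifest.
    """
    df = manifest.sort_genomic().table
    slk_p = np.asarray(slk_p, dtype=float)
    pos = df["pos"].to_numpy()
    chrom = df["chrom"].to_numpy()
    regions: list[dict] = []
    i, n = 0, len(df)
    while i < n:
        if slk_p[i] >= seed_p:
            i += 1
            continue
        j = i
        while (j + 1 < n and chrom[j + 1] == chrom[j]
               and slk_p[j + 1] < seed_p and pos[j + 1] - pos[j] <= dist):
            j += 1
        if j - i + 1 >= min_probes:
            regions.append({
                "chrom": str(chrom[i]),
                "start": int(pos[i]),
                "end": int(pos[j]),
                "indices": list(range(i, j + 1)),
            })
        i = j + 1
    return regions


def region_significance(
    indices,
    original_p: np.ndarray,
    manifest: ProbeManifest,
    acf: ACFEstimate,
) -> float:
    """Stouffer-Liptak combination of a region's original p-values."""
    df = manifest.sort_genomic().table
    idx = list(indices)
    pvals = np.asarray(original_p, dtype=float)[idx]
    pos = df["pos"].to_numpy()[idx]
    d = np.abs(pos[:, None] - pos[None, :])
    sigma = acf.lookup(d)
    np.fill_diagonal(sigma, 1.0)
    return stouffer_liptak(pvals, sigma)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _annotate(
    region: dict,
    p_region: float,
    p_sidak: float,
    matrix: BetaMatrix,
    manifest_sorted: ProbeManifest,
    sheet: SampleSheet,
) -> DMR:
    probes = [manifest_sorted.probe_ids[i] for i in region["indices"]]
    sub = matrix.values.loc[probes]
    case = sheet.is_case()
    case_ids = [s for s, c in zip(sheet.sample_ids, case) if c]
    ctrl_ids = [s for s, c in zip(sheet.sample_ids, case) if not c]
    diffs = sub[case_ids].mean(axis=1) - sub[ctrl_ids].mean(axis=1)
    mean_diff = float(diffs.mean())
    largest = float(diffs.iloc[int(np.argmax(np.abs(diffs.to_numpy())))])
    ann = manifest_sorted.table.loc[probes]

    def _union(series_of_lists):
        seen: list[str] = []
        for items in series_of_lists:
            values = items if isinstance(items, (list, tuple)) else [items]
            for v in values:
                if v and v not in seen:
                    seen.append(v)
        return seen

    return DMR(
        chrom=region["chrom"],
        start=region["start"],
        end=region["end"],
        probe_ids=probes,
        p_region=p_region,
        p_sidak=p_sidak,
        mean_beta=float(sub.to_numpy().mean()),
        mean_diff=mean_diff,
        largest_diff=largest,
        direction="hyper" if mean_diff > 0 else "hypo",
        genes=_union(ann["genes"]),
        gene_regions=_union(ann["gene_region"]),
        island_relations=_union(ann["island_relation"]),
    )


def call_dmrs(
    site_p: np.ndarray,
    matrix: BetaMatrix,
    manifest: ProbeManifest,
    sheet: SampleSheet,
    dist: int = 1000,
    seed_p: float = 0.05,
    bin_width: int = 50,
    min_probes: int = 2,
    min_pairs: int = 10,
    sidak_alpha: float | None = None,
) -> tuple[list[DMR], dict]:
    """Full region-calling chain from per-probe p-values.

    ``site_p`` must align with ``matrix.probe_ids``; the matrix must be
    restricted to analyzed probes and is re-sorted genomically
    internally.  The Sidak totality is the probe-covered span per
    chromosome (last minus first analyzed position plus one), summed.
    Returns the regions sorted by Sidak p ascending (optionally filtered
    at ``sidak_alpha``) plus a dict of per-stage intermediates for audit
    (ACF estimate, SLK p-values, candidate count, total span).
    """
    site_p = np.asarray(site_p, dtype=float)
    if len(site_p) != matrix.n_probes:
        raise ParameterError("site_p length does not match matrix probes")
    manifest_sub = manifest.restrict(matrix.probe_ids).sort_genomic()
    pidx = {p: i for i, p in enumerate(matrix.probe_ids)}
    order = [pidx[p] for p in manifest_sub.probe_ids]
    p_sorted = site_p[order]
    matrix_sorted = matrix.restrict(manifest_sub.probe_ids)

    acf = estimate_acf(p_sorted, manifest_sub, dist=dist, bin_width=bin_width,
                       min_pairs=min_pairs)
    slk_p = slk_correct(p_sorted, manifest_sub, acf, dist=dist)
    candidates = find_candidate_regions(slk_p, manifest_sub, seed_p=seed_p,
                                        dist=dist, min_probes=min_probes)

    df = manifest_sub.table
    total_len = int(
        df.groupby("chrom")["pos"].agg(lambda s: s.max() - s.min() + 1).sum()
    )
    dmrs: list[DMR] = []
    for region in candidates:
        p_reg = region_significance(region["indices"], p_sorted, manifest_sub, acf)
        span = region["end"] - region["start"] + 1
        p_sid = sidak_correct(p_reg, span, max(total_len, span))
        dmrs.append(_annotate(region, p_reg, p_sid, matrix_sorted,
                              manifest_sub, sheet))
    dmrs.sort(key=lambda d: (d.p_sidak, d.chrom, d.start))
    if sidak_alpha is not None:
        dmrs = [d for d in dmrs if d.p_sidak < sidak_alpha]
    audit = {"acf": acf, "slk_p": slk_p, "n_candidates": len(candidates),
             "total_len": total_len, "manifest_sorted": manifest_sub}
    return dmrs, audit


def hypermethylated_fraction(dmrs) -> float:
    """Fraction of called regions hypermethylated in cases."""
    dmrs = list(dmrs)
    if not dmrs:
        raise ParameterError("no DMRs given")
    return sum(1 for d in dmrs if d.direction == "hyper") / len(dmrs)
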