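"""Guide-level fold changes and gene-level Bayes-factor lethality scores.

The classifier is a supervised likelihood-ratio scheme: kernel density
estimates of the guide fold-change distribution are fitted on reference
essential and non-essential training genes, and each gene's score is the
summed log2 likelihood ratio of its guides' fold changes under the two
densities.  Positive scores (bits) favour essentiality.

Replicate cell lines are scored separately and aggregated per genotype
(arithmetic mean by default); a parametric-density hook lets the scoring
core be verified against Gaussian closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .screen_model import (
    CountMatrix,
    GuideLibrary,
    ReferenceGeneSets,
    SampleSheet,
)

__all__ = [
    "FoldChangeTable",
    "GaussianKde",
    "ParametricDensity",
    "DensityPair",
    "monotone_lr_envelope",
    "BootstrapConfig",
    "guide_log_fold_change",
    "fit_densities",
    "gene_bayes_factor",
    "genotype_bf",
    "score_screen",
    "silverman_bandwidth",
]

DENSITY_FLOOR = 1e-12


@dataclass(frozen=True)
class FoldChangeTable:
    """Per-guide log2 fold changes vs the plasmid reference.

    ``fc`` is guides x samples (plasmid column excluded); the pseudocount
    and scale used are carried so the table is reproducible from counts.
    """

    fc: pd.DataFrame
    plasmid_sample: str
    alpha: float
    scale: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fc.columns)

    def values_for(self, guide_ids: Sequence[str], samples: Sequence[str]) -> np.ndarray:
        return self.fc.loc[list(guide_ids), list(samples)].to_numpy()


def guide_log_fold_change(
    counts: CountMatrix,
    plasmid_sample: str,
    alpha: float = 5.0,
    scale: float = 1e7,
) -> FoldChangeTable:
    """log2 fold change of each guide in each sample vs the plasmid library.

    fc(g, s) = log2((c_gs + alpha) * scale / depth_s)
             - log2((c_gp + alpha) * scale / depth_p)

    The pseudocount ``alpha > 0`` keeps zero counts finite.
    """
    if alpha <= 0:
        raise ValueError("pseudocount alpha must be > 0")
    if plasmid_sample not in counts.sample_ids:
        raise ValueError(f"plasmid sample {plasmid_sample!r} not in count matrix")
    depth = counts.depth
    samples = [s for s in counts.sample_ids if s != plasmid_sample]
    for s in samples + [plasmid_sample]:
        if depth[s] == 0:
            raise ValueError(f"sample {s!r} has zero depth")
    plasmid_norm = np.log2(
        (counts.column(plasmid_sample) + alpha) * scale / depth[plasmid_sample]
    )
    data = {
        s: np.log2((counts.column(s) + alpha) * scale / depth[s]) - plasmid_norm
        for s in samples
    }
    fc = pd.DataFrame(data, index=pd.Index(counts.guide_ids, name="guide_id"))
    return FoldChangeTable(fc=fc, plasmid_sample=plasmid_sample, alpha=alpha, scale=scale)


# ---------------------------------------------------------------------------
# Densities


def silverman_bandwidth(data: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    data = np.asarray(data, dtype=float)
    n = data.size
    if n < 2:
        raise ValueError("need >= 2 points for a bandwidth")
    sd = data.std(ddof=1)
    q75, q25 = np.percentile(data, [75, 25])
    iqr = q75 - q25
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    if spread == 0:
        raise ValueError("degenerate training data: zero spread")
    return 0.9 * spread * n ** (-0.2)


class GaussianKde:
    """1-D Gaussian kernel density with a support clamp and evaluation floor.

    Evaluation points are clipped into ``[lo, hi]`` (the training range
    padded by several bandwidths) so far-tail observations get the boundary
    density rather than underflowing; the floor keeps log ratios finite.
    """

    def __init__(
        self,
        data: Iterable[float],
        bandwidth: float | str = "silverman",
        floor: float = DENSITY_FLOOR,
        clamp_pad: float = 3.0,
    ):
        self.data = np.sort(np.asarray(list(data), dtype=float))
        if self.data.size == 0:
            raise ValueError("no training data")
        if bandwidth == "silverman":
            self.bandwidth = silverman_bandwidth(self.data)
        else:
            self.bandwidth = float(bandwidth)
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        self.floor = float(floor)
        self.lo = float(self.data[0] - clamp_pad * self.bandwidth)
        self.hi = float(self.data[-1] + clamp_pad * self.bandwidth)

    def evaluate(self, x: np.ndarray | float) -> np.ndarray:
        x = np.clip(np.atleast_1d(np.asarray(x, dtype=float)), self.lo, self.hi)
        h = self.bandwidth
        z = (x[:, None] - self.data[None, :]) / h
        dens = np.exp(-0.5 * z * z).sum(axis=1) / (self.data.size * h * math.sqrt(2 * math.pi))
        return np.maximum(dens, self.floor)

    __call__ = evaluate


class ParametricDensity:
    """Closed-form density hook (e.g. a Gaussian) for verifying the scorer."""

    def __init__(self, pdf: Callable[[np.ndarray], np.ndarray], floor: float = DENSITY_FLOOR):
        self._pdf = pdf
        self.floor = float(floor)
        self.bandwidth = float("nan")
        self.lo, self.hi = -math.inf, math.inf

    def evaluate(self, x: np.ndarray | float) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.maximum(np.asarray(self._pdf(x), dtype=float), self.floor)

    __call__ = evaluate


@dataclass(frozen=True)
class DensityPair:
    """Essential / non-essential fold-change densities.

    When a monotone envelope grid is attached (see
    :func:`monotone_lr_envelope`), the log2 likelihood ratio is evaluated by
    interpolation on that non-increasing envelope instead of the raw density
    ratio.  This bounds the LR on both sides: deeply depleted observations
    all receive the capped maximum, and enrichment cannot masquerade as
    essentiality through a kernel-tail artifact.
    """

    essential: GaussianKde | ParametricDensity
    nonessential: GaussianKde | ParametricDensity
    monotone_grid: tuple[np.ndarray, np.ndarray] | None = None

    def raw_log2_ratio(self, x: np.ndarray | float) -> np.ndarray:
        """log2 p_ess(x) / p_non(x) straight from the densities."""
        return np.log2(self.essential(x)) - np.log2(self.nonessential(x))

    def log2_ratio(self, x: np.ndarray | float) -> np.ndarray:
        """Per-observation log2 likelihood ratio (bits, essential over non)."""
        if self.monotone_grid is None:
            return self.raw_log2_ratio(x)
        xs, lr = self.monotone_grid
        return np.interp(np.atleast_1d(np.asarray(x, dtype=float)), xs, lr)


def monotone_lr_envelope(pair: DensityPair, n_grid: int = 4096) -> DensityPair:
    """Return the pair with a monotone non-increasing log-ratio envelope.

    The raw KDE log ratio is evaluated on a grid spanning both supports,
    capped at its maximum on the left (more depletion cannot reduce the
    evidence) and made non-increasing by a running minimum to the right.
    Interpolation extends flatly beyond the grid.
    """
    lo = min(pair.essential.lo, pair.nonessential.lo)
    hi = max(pair.essential.hi, pair.nonessential.hi)
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError("monotone envelope needs finite density supports")
    xs = np.linspace(lo, hi, n_grid)
    lr = pair.raw_log2_ratio(xs)
    peak = int(np.argmax(lr))
    lr[:peak] = lr[peak]
    lr = np.minimum.accumulate(lr)
    return DensityPair(
        essential=pair.essential,
        nonessential=pair.nonessential,
        monotone_grid=(xs, lr),
    )


def _training_guides(
    library: GuideLibrary, genes: Iterable[str]
) -> list[str]:
    out: list[str] = []
    for gene in genes:
        out.extend(library.guides_for(gene))
    return out


def fit_densities(
    fc: FoldChangeTable,
    library: GuideLibrary,
    refsets: ReferenceGeneSets,
    samples: Sequence[str] | None = None,
    bandwidth: float | str = "silverman",
    floor: float = DENSITY_FLOOR,
    min_training_guides: int = 10,
    monotone: bool = True,
) -> DensityPair:
    """Fit the essential/non-essential KDE pair on reference-gene fold changes.

    Training fold changes are pooled over ``samples`` (default: all columns).
    Both classes share one bandwidth, computed by the stated rule on the
    union of their training values: unequal per-class smoothing puts
    spurious structure into the likelihood ratio (the narrow non-essential
    class would otherwise dominate the ratio's steepness).  Reference genes
    absent from the library are dropped; an under-populated class aborts
    with the class named.  ``monotone`` attaches the non-increasing
    log-ratio envelope used for scoring (the raw densities remain available
    on the returned pair).
    """
    if samples is None:
        samples = fc.sample_ids
    restricted = refsets.restrict_to(library.gene_index)
    training: dict[str, np.ndarray] = {}
    for name, genes in (
        ("essential", restricted.essential),
        ("nonessential", restricted.nonessential),
    ):
        guides = _training_guides(library, sorted(genes))
        if len(guides) < min_training_guides:
            raise ValueError(
                f"{name} training class has {len(guides)} guides "
                f"(< {min_training_guides}) after library intersection"
            )
        training[name] = fc.values_for(guides, samples).ravel()
    if bandwidth == "silverman":
        shared_bw: float = silverman_bandwidth(
            np.concatenate([training["essential"], training["nonessential"]])
        )
    else:
        shared_bw = float(bandwidth)
    pair = DensityPair(
        essential=GaussianKde(training["essential"], bandwidth=shared_bw, floor=floor),
        nonessential=GaussianKde(training["nonessential"], bandwidth=shared_bw, floor=floor),
    )
    return monotone_lr_envelope(pair) if monotone else pair


# ---------------------------------------------------------------------------
# Bayes factors


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap over training genes for BF uncertainty.

    ``resample=False`` degenerates to refitting on the full training set
    every iteration (a deterministic path used for verification).
    """

    n_iter: int = 200
    refsets: ReferenceGeneSets | None = None
    bandwidth: float | str = "silverman"
    floor: float = DENSITY_FLOOR
    resample: bool = True
    monotone: bool = True


def _bf_from_densities(
    fc_values: dict[str, np.ndarray], densities: DensityPair
) -> pd.Series:
    genes = list(fc_values)
    if not genes:
        return pd.Series(dtype=float)
    flat = np.concatenate([fc_values[g] for g in genes])
    lr = densities.log2_ratio(flat)
    sizes = [fc_values[g].size for g in genes]
    offsets = np.cumsum([0] + sizes)
    return pd.Series(
        {g: lr[offsets[i] : offsets[i + 1]].sum() for i, g in enumerate(genes)},
        dtype=float,
    )


def gene_bayes_factor(
    fc: FoldChangeTable,
    densities: DensityPair,
    library: GuideLibrary,
    samples: Sequence[str] | None = None,
    bootstrap: BootstrapConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-gene BF: sum of log2 likelihood ratios over guide x sample
    fold changes.  Control guides never contribute; genes without usable
    guides are absent from the output (not zero).

    Returns a frame indexed by gene with columns ``bf`` and ``n_guides``
    (plus ``boot_mean``/``boot_sd`` when bootstrapping).
    """
    if samples is None:
        samples = fc.sample_ids
    fc_values: dict[str, np.ndarray] = {}
    n_guides: dict[str, int] = {}
    for gene in library.targeting_genes:
        guides = [g for g in library.guides_for(gene) if g in fc.fc.index]
        if not guides:
            continue
        fc_values[gene] = fc.values_for(guides, samples).ravel()
        n_guides[gene] = len(guides)
    bf = _bf_from_densities(fc_values, densities)
    out = pd.DataFrame({"bf": bf, "n_guides": pd.Series(n_guides)})
    out.index.name = "gene"

    if bootstrap is not None and bootstrap.n_iter > 0:
        if bootstrap.refsets is None:
            raise ValueError("bootstrap requires reference gene sets to resample")
        rng = np.random.default_rng(seed)
        restricted = bootstrap.refsets.restrict_to(library.gene_index)
        ess = sorted(restricted.essential)
        non = sorted(restricted.nonessential)

        def gene_values(g: str) -> np.ndarray:
            if g in fc_values:
                return fc_values[g]
            return fc.values_for(library.guides_for(g), samples).ravel()

        draws = np.empty((bootstrap.n_iter, len(out)))
        for it in range(bootstrap.n_iter):
            if bootstrap.resample:
                ess_it = list(rng.choice(ess, size=len(ess), replace=True))
                non_it = list(rng.choice(non, size=len(non), replace=True))
            else:
                ess_it, non_it = ess, non
            ev = np.concatenate([gene_values(g) for g in ess_it])
            nv = np.concatenate([gene_values(g) for g in non_it])
            bw = (
                silverman_bandwidth(np.concatenate([ev, nv]))
                if bootstrap.bandwidth == "silverman"
                else float(bootstrap.bandwidth)
            )
            pair = DensityPair(
                essential=GaussianKde(ev, bandwidth=bw, floor=bootstrap.floor),
                nonessential=GaussianKde(nv, bandwidth=bw, floor=bootstrap.floor),
            )
            if bootstrap.monotone:
                pair = monotone_lr_envelope(pair)
            draws[it] = _bf_from_densities(fc_values, pair).reindex(out.index).to_numpy()
        out["boot_mean"] = draws.mean(axis=0)
        out["boot_sd"] = draws.std(axis=0, ddof=1) if bootstrap.n_iter > 1 else 0.0
    return out


def genotype_bf(
    per_line: pd.DataFrame,
    sheet: SampleSheet,
    aggregation: str = "mean",
) -> pd.DataFrame:
    """Aggregate per-replicate-line BF into one value per (gene, genotype).

    ``per_line`` needs columns ``gene``, ``sample``, ``bf``.  Aggregations:
    ``mean`` (default), ``median``, ``pooled`` (sum of per-line BF, i.e.
    log-ratio pooling across lines).
    """
    if aggregation not in ("mean", "median", "pooled"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    df = per_line.copy()
    df["genotype"] = [sheet.genotype_of(s) for s in df["sample"]]
    agg = {"mean": "mean", "median": "median", "pooled": "sum"}[aggregation]
    wide = df.pivot_table(index="gene", columns="genotype", values="bf", aggfunc=agg)
    wide.columns.name = None
    return wide


def score_screen(
    counts: CountMatrix,
    sheet: SampleSheet,
    library: GuideLibrary,
    refsets: ReferenceGeneSets,
    alpha: float = 5.0,
    scale: float = 1e7,
    bandwidth: float | str = "silverman",
    floor: float = DENSITY_FLOOR,
    aggregation: str = "mean",
    bootstrap: BootstrapConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts -> per-genotype BF table.

    One density pair is fitted on training fold changes pooled across all
    replicate lines (both genotypes see the identical likelihood-ratio
    curve, so no density-estimation jitter leaks into the genotype
    contrast); each line is then scored separately and aggregated per
    genotype.

    Returns ``(genotype_table, per_line_table)`` where the genotype table is
    genes x {knockout, wildtype} and the per-line table is long-form.
    """
    fc = guide_log_fold_change(counts, sheet.plasmid_sample, alpha=alpha, scale=scale)
    line_samples = [s for s in fc.sample_ids if sheet.genotype_of(s) != "plasmid"]
    pair = fit_densities(
        fc, library, refsets, samples=line_samples, bandwidth=bandwidth, floor=floor
    )
    rows = []
    for sample_id in line_samples:
        table = gene_bayes_factor(
            fc, pair, library, samples=[sample_id], bootstrap=bootstrap, seed=seed
        )
        table = table.reset_index()
        table["sample"] = sample_id
        rows.append(table)
    per_line = pd.concat(rows, ignore_index=True)
    return genotype_bf(per_line, sheet, aggregation=aggregation), per_line
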