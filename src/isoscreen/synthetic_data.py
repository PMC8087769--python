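"""Seeded generative model of an isogenic-pair dropout screen.

The simulator emulates the screen design end to end — plasmid library with
log-normal abundance skew, an infection bottleneck at the configured
coverage, exponential growth over a fixed number of doublings with
per-guide knockout efficiency, and multinomial sequencing — and exports the
planted ground truth so recovery can be scored.

Growth model per guide g in genotype y, after d doublings (relative to a
neutral guide):

    factor(g, y) = e_g * 2^(d * f(gene(g), y)) + (1 - e_g)

where e_g is the guide's knockout efficiency and f is the per-doubling
log2 fitness effect of losing the gene in that genotype.  The two-component
mixture reflects cells that escape editing and grow normally.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .screen_model import (
    CONTROL_GENE,
    CountMatrix,
    GuideLibrary,
    GuideRecord,
    ReferenceGeneSets,
    SampleRecord,
    SampleSheet,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedScreen",
    "RecoveryReport",
    "generate_library",
    "generate_truth",
    "simulate_screen",
    "simulate",
    "write_fastq",
    "evaluate_recovery",
    "reference_sets_from_truth",
    "expected_log2_fold_change",
]

GENE_CLASSES = ("neutral", "core_essential", "ko_specific", "wt_specific", "enriched_on_loss")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Screen-design and effect-model parameters (desk scale by default)."""

    n_genes: int = 2000
    guides_per_gene: tuple[int, int] = (3, 5)
    n_control_guides: int = 100
    spacer_length: int = 20
    coverage: int = 200            # cells per guide at infection
    transduction_fraction: float = 0.30
    selection_day: int = 2
    doublings: float = 16.0
    passage_floor: int = 500       # cells per guide maintained at passaging
    depth: int = 5_000_000         # sequenced reads per sample
    plasmid_sigma: float = 0.5     # log-normal sigma of plasmid abundances
    efficiency_beta: tuple[float, float] = (5.0, 2.0)
    n_lines: int = 3               # clonal replicate lines per genotype
    line_sigma: float = 0.0        # optional per-line log-normal jitter
    # planted effect classes (per-doubling log2 fitness effects)
    n_core_essential: int = 100
    f_core: float = -0.3
    n_ko_specific: int = 50
    f_ko: float = -0.2
    n_wt_specific: int = 0
    f_wt: float = -0.2
    n_enriched: int = 0
    f_enriched: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.guides_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("guides_per_gene range must satisfy 1 <= lo <= hi")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 < self.transduction_fraction <= 1:
            raise ValueError("transduction_fraction must be in (0, 1]")
        if self.doublings < 0:
            raise ValueError("doublings must be >= 0")
        for name in ("f_core", "f_ko", "f_wt"):
            if getattr(self, name) < -1:
                raise ValueError(f"{name} < -1: below the extinction floor; "
                                 "model partial dropout via guide efficiency")
        planted = self.n_core_essential + self.n_ko_specific + self.n_wt_specific + self.n_enriched
        if planted > self.n_genes:
            raise ValueError("more planted effect genes than genes")


@dataclass(frozen=True)
class SimTruth:
    """Planted per-gene classes/effects and per-guide efficiencies."""

    genes: pd.DataFrame       # index gene; columns class, f_knockout, f_wildtype
    guide_efficiency: pd.Series  # index guide_id

    def __post_init__(self) -> None:
        unknown = set(self.genes["class"]) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        for col in ("f_knockout", "f_wildtype"):
            if (self.genes[col] < -1).any():
                raise ValueError(f"{col} < -1: below the extinction floor")
        neutral = self.genes["class"] == "neutral"
        if (self.genes.loc[neutral, ["f_knockout", "f_wildtype"]] != 0).any().any():
            raise ValueError("neutral genes must have zero fitness effect")

    def genes_of_class(self, cls: str) -> list[str]:
        return list(self.genes.index[self.genes["class"] == cls])


@dataclass(frozen=True)
class SimulatedScreen:
    """A complete synthetic screen plus everything needed to verify it."""

    library: GuideLibrary
    truth: SimTruth
    counts: CountMatrix
    sheet: SampleSheet
    expected_fractions: pd.DataFrame  # guides x samples, noise-free abundances
    config: SimConfig
    seed: int


@dataclass(frozen=True)
class RecoveryReport:
    """Precision/recall of dependency calls against planted truth."""

    n_positive: int
    n_called: int
    n_true_positive: int
    per_class_calls: dict[str, int]

    @property
    def precision(self) -> float | None:
        return self.n_true_positive / self.n_called if self.n_called else None

    @property
    def recall(self) -> float | None:
        return self.n_true_positive / self.n_positive if self.n_positive else None


# ---------------------------------------------------------------------------
# Library & truth generation


def _random_spacers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    if n > 4**length:
        raise ValueError(f"cannot draw {n} unique spacers of length {length}")
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), length))
        for row in block:
            s = "".join(_BASES[row])
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def generate_library(config: SimConfig, seed: int) -> GuideLibrary:
    """Random unique-spacer library; guides per gene uniform over the range."""
    rng = np.random.default_rng(seed)
    lo, hi = config.guides_per_gene
    n_per_gene = rng.integers(lo, hi + 1, size=config.n_genes)
    total = int(n_per_gene.sum()) + config.n_control_guides
    spacers = _random_spacers(rng, total, config.spacer_length)
    records = []
    cursor = 0
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        gene = f"GENE{i + 1:0{width}d}"
        for j in range(n_per_gene[i]):
            records.append(
                GuideRecord(f"{gene}_g{j + 1}", gene, spacers[cursor], "targeting")
            )
            cursor += 1
    for j in range(config.n_control_guides):
        records.append(
            GuideRecord(f"CTRL_g{j + 1}", CONTROL_GENE, spacers[cursor], "control")
        )
        cursor += 1
    return GuideLibrary(records)


def generate_truth(library: GuideLibrary, config: SimConfig, seed: int) -> SimTruth:
    """Assign planted classes to random genes and draw guide efficiencies."""
    rng = np.random.default_rng(seed)
    genes = library.targeting_genes
    order = rng.permutation(len(genes))
    classes = pd.Series("neutral", index=pd.Index(genes, name="gene"))
    cursor = 0
    for cls, n in (
        ("core_essential", config.n_core_essential),
        ("ko_specific", config.n_ko_specific),
        ("wt_specific", config.n_wt_specific),
        ("enriched_on_loss", config.n_enriched),
    ):
        chosen = [genes[i] for i in order[cursor : cursor + n]]
        classes.loc[chosen] = cls
        cursor += n
    f_ko = pd.Series(0.0, index=classes.index)
    f_wt = pd.Series(0.0, index=classes.index)
    f_ko[classes == "core_essential"] = config.f_core
    f_wt[classes == "core_essential"] = config.f_core
    f_ko[classes == "ko_specific"] = config.f_ko
    f_wt[classes == "wt_specific"] = config.f_wt
    f_ko[classes == "enriched_on_loss"] = config.f_enriched
    a, b = config.efficiency_beta
    eff = pd.Series(
        rng.beta(a, b, size=len(library)),
        index=pd.Index(library.guide_ids, name="guide_id"),
    )
    genes_df = pd.DataFrame(
        {"class": classes, "f_knockout": f_ko, "f_wildtype": f_wt}
    )
    return SimTruth(genes=genes_df, guide_efficiency=eff)


# ---------------------------------------------------------------------------
# Screen dynamics


def _largest_remainder_round(p: np.ndarray, total: int) -> np.ndarray:
    """Round total*p to integers summing exactly to total (deterministic)."""
    exact = p * total
    base = np.floor(exact).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        frac = exact - base
        top = np.argsort(-frac, kind="stable")[:short]
        base[top] += 1
    return base


def _growth_factor(
    library: GuideLibrary, truth: SimTruth, genotype: str, doublings: float
) -> np.ndarray:
    f_col = {"knockout": "f_knockout", "wildtype": "f_wildtype"}[genotype]
    f = np.array(
        [
            truth.genes.at[r.gene, f_col] if r.gene != CONTROL_GENE else 0.0
            for r in library.records
        ]
    )
    e = truth.guide_efficiency.loc[library.guide_ids].to_numpy()
    return e * np.exp2(doublings * f) + (1.0 - e)


def simulate_screen(
    library: GuideLibrary,
    truth: SimTruth,
    config: SimConfig,
    seed: int,
    deterministic: bool = False,
) -> SimulatedScreen:
    """Run the infection -> selection -> growth -> sequencing model.

    ``deterministic=True`` replaces every sampling step with its expectation
    (largest-remainder rounding for integer counts), making fold changes
    match the closed-form growth factors exactly via ``expected_fractions``.
    """
    missing = set(library.targeting_genes) - set(truth.genes.index)
    if missing:
        raise ValueError(f"truth missing genes: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    n_guides = len(library)

    w = rng.lognormal(0.0, config.plasmid_sigma, size=n_guides)
    p_plasmid = w / w.sum()

    sample_ids = ["plasmid"]
    sample_records = [SampleRecord("plasmid", "plasmid", "lib", 0.0)]
    columns: dict[str, np.ndarray] = {}
    fractions: dict[str, np.ndarray] = {"plasmid": p_plasmid}
    if deterministic:
        columns["plasmid"] = _largest_remainder_round(p_plasmid, config.depth)
    else:
        columns["plasmid"] = rng.multinomial(config.depth, p_plasmid)

    pool = config.coverage * n_guides  # infected cells surviving selection
    factors = {
        g: _growth_factor(library, truth, g, config.doublings)
        for g in ("knockout", "wildtype")
    }
    for genotype, tag in (("knockout", "ko"), ("wildtype", "wt")):
        factor = factors[genotype]
        expected = p_plasmid * factor
        expected /= expected.sum()
        for line in range(1, config.n_lines + 1):
            sid = f"{tag}_{line}"
            sample_ids.append(sid)
            sample_records.append(SampleRecord(sid, genotype, str(line), 21.0))
            fractions[sid] = expected
            if deterministic:
                columns[sid] = _largest_remainder_round(expected, config.depth)
            else:
                n0 = rng.multinomial(pool, p_plasmid).astype(float)
                abundance = n0 * factor
                if config.line_sigma > 0:
                    abundance *= rng.lognormal(0.0, config.line_sigma, size=n_guides)
                columns[sid] = rng.multinomial(config.depth, abundance / abundance.sum())

    counts = CountMatrix(
        library.guide_ids,
        sample_ids,
        np.column_stack([columns[s] for s in sample_ids]),
    )
    sheet = SampleSheet(sample_records)
    expected_fractions = pd.DataFrame(
        {s: fractions[s] for s in sample_ids},
        index=pd.Index(library.guide_ids, name="guide_id"),
    )
    return SimulatedScreen(
        library=library,
        truth=truth,
        counts=counts,
        sheet=sheet,
        expected_fractions=expected_fractions,
        config=config,
        seed=seed,
    )


def simulate(config: SimConfig, seed: int, deterministic: bool = False) -> SimulatedScreen:
    """Library + truth + screen in one seeded call (sub-seeds are derived)."""
    ss = np.random.SeedSequence(seed).spawn(3)
    lib_seed, truth_seed, screen_seed = (int(s.generate_state(1)[0]) for s in ss)
    library = generate_library(config, lib_seed)
    truth = generate_truth(library, config, truth_seed)
    return simulate_screen(library, truth, config, screen_seed, deterministic=deterministic)


def expected_log2_fold_change(screen: SimulatedScreen) -> pd.DataFrame:
    """Noise-free log2 fold change of each guide vs the plasmid column."""
    f = screen.expected_fractions
    plasmid = f["plasmid"]
    others = [c for c in f.columns if c != "plasmid"]
    return np.log2(f[others].div(plasmid, axis=0))


# ---------------------------------------------------------------------------
# FASTQ export


def _random_nonmatching_read(
    rng: np.random.Generator, length: int, spacers: set[str], spacer_len: int
) -> str:
    while True:
        read = "".join(_BASES[rng.integers(0, 4, size=length)])
        if not any(
            read[i : i + spacer_len] in spacers for i in range(length - spacer_len + 1)
        ):
            return read


def write_fastq(
    screen: SimulatedScreen,
    out_dir: str | Path,
    flank5: str = "ACCG",
    flank3: str = "GTTTAAGAGC",
    seed: int = 0,
    decoy_fraction: float = 0.0,
    gzip_output: bool = False,
) -> dict[str, Path]:
    """Emit exactly count(g, s) reads carrying guide g's spacer per sample.

    Reads are ``flank5 + spacer + flank3`` in shuffled order; decoys are
    random reads guaranteed to contain no spacer.  Round-tripping through
    the quantifier recovers the counts exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    spacers = {r.sequence for r in screen.library.records}
    spacer_len = screen.library.max_guide_length()
    paths: dict[str, Path] = {}
    for sample_id in screen.counts.sample_ids:
        col = screen.counts.column(sample_id)
        reads = [
            flank5 + rec.sequence + flank3
            for rec, c in zip(screen.library.records, col)
            for _ in range(int(c))
        ]
        n_decoys = int(round(decoy_fraction * len(reads)))
        read_len = len(flank5) + spacer_len + len(flank3)
        reads += [
            _random_nonmatching_read(rng, read_len, spacers, spacer_len)
            for _ in range(n_decoys)
        ]
        rng.shuffle(reads)
        suffix = ".fastq.gz" if gzip_output else ".fastq"
        path = out_dir / f"{sample_id}{suffix}"
        opener = gzip.open if gzip_output else open
        with opener(path, "wt") as fh:  # type: ignore[operator]
            for i, seq in enumerate(reads):
                fh.write(f"@{sample_id}.{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths[sample_id] = path
    return paths


# ---------------------------------------------------------------------------
# Scoring against truth


def reference_sets_from_truth(
    truth: SimTruth, n_nonessential: int = 500, seed: int = 0
) -> ReferenceGeneSets:
    """Training sets for synthetic runs: planted core-essential genes as
    essential, a random draw of neutral genes as non-essential."""
    rng = np.random.default_rng(seed)
    essential = truth.genes_of_class("core_essential")
    neutral = truth.genes_of_class("neutral")
    n = min(n_nonessential, len(neutral))
    nonessential = list(rng.choice(neutral, size=n, replace=False))
    return ReferenceGeneSets(frozenset(essential), frozenset(nonessential))


def evaluate_recovery(truth: SimTruth, calls: pd.DataFrame) -> RecoveryReport:
    """Score ``is_dependency`` calls against planted ko_specific genes."""
    stray = set(calls.index) - set(truth.genes.index)
    if stray:
        raise ValueError(f"called genes absent from truth: {sorted(stray)[:5]}")
    positives = set(truth.genes_of_class("ko_specific"))
    called = set(calls.index[calls["is_dependency"]])
    per_class = {
        cls: sum(1 for g in called if truth.genes.at[g, "class"] == cls)
        for cls in GENE_CLASSES
    }
    return RecoveryReport(
        n_positive=len(positives),
        n_called=len(called),
        n_true_positive=len(called & positives),
        per_class_calls=per_class,
    )
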