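"""Domain types and tabular I/O shared by every pipeline stage.

All interchange is plain TSV:

* guide library   — columns ``guide_id, gene, sequence[, guide_class]``
* count matrix    — ``guide_id`` plus one integer column per sample
* sample sheet    — ``sample_id, genotype, replicate, timepoint_days``
* reference sets  — one gene symbol per line

Validation is strict where ambiguity would corrupt counts downstream
(duplicate spacers, duplicate guide ids) and lenient-with-warning where a
record can simply be dropped (a reference gene missing from the library).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL_GENE",
    "GENOTYPES",
    "GuideRecord",
    "GuideLibrary",
    "SampleRecord",
    "SampleSheet",
    "CountMatrix",
    "ReferenceGeneSets",
    "ValidationIssue",
    "ValidationReport",
    "FormatError",
    "LibraryValidationError",
    "read_library",
    "write_library",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_list",
    "write_gene_list",
    "validate_inputs",
]

#: Reserved gene label for non-targeting control guides.  Double underscores
#: keep it out of any real gene-symbol namespace.
CONTROL_GENE = "__control__"

GENOTYPES = ("knockout", "wildtype", "plasmid")

_DNA = frozenset("ACGT")


class FormatError(ValueError):
    """A file does not conform to the expected tabular schema."""


class LibraryValidationError(ValueError):
    """A guide library violates an integrity invariant."""


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA: identifier, target gene, spacer sequence, class."""

    guide_id: str
    gene: str
    sequence: str
    guide_class: str = "targeting"

    def __post_init__(self) -> None:
        if not self.guide_id:
            raise LibraryValidationError("empty guide_id")
        if not self.sequence:
            raise LibraryValidationError(f"guide {self.guide_id!r}: empty sequence")
        bad = set(self.sequence) - _DNA
        if bad:
            raise LibraryValidationError(
                f"guide {self.guide_id!r}: non-ACGT characters {sorted(bad)!r} "
                f"in sequence {self.sequence!r}"
            )
        if not 19 <= len(self.sequence) <= 20:
            raise LibraryValidationError(
                f"guide {self.guide_id!r}: spacer length {len(self.sequence)} "
                "outside 19-20 nt"
            )
        if self.guide_class not in ("targeting", "control"):
            raise LibraryValidationError(
                f"guide {self.guide_id!r}: unknown guide_class {self.guide_class!r}"
            )
        if self.guide_class == "control":
            if self.gene != CONTROL_GENE:
                object.__setattr__(self, "gene", CONTROL_GENE)
        elif self.gene == CONTROL_GENE:
            raise LibraryValidationError(
                f"guide {self.guide_id!r}: targeting guide uses the reserved "
                f"control gene label {CONTROL_GENE!r}"
            )


class GuideLibrary:
    """Ordered, integrity-checked collection of :class:`GuideRecord`.

    Duplicate guide ids and duplicate spacer sequences are rejected at
    construction: a read matching two guides cannot be attributed, so
    ambiguity is fatal rather than silently tolerated.
    """

    def __init__(self, records: Iterable[GuideRecord]):
        self.records: list[GuideRecord] = list(records)
        if not self.records:
            raise LibraryValidationError("library has no records")
        self._check_unique("guide_id", [r.guide_id for r in self.records])
        self._check_unique("sequence", [r.sequence for r in self.records])
        self._by_id = {r.guide_id: r for r in self.records}
        self.gene_index: dict[str, list[str]] = {}
        for r in self.records:
            self.gene_index.setdefault(r.gene, []).append(r.guide_id)

    def _check_unique(self, what: str, values: Sequence[str]) -> None:
        seen: dict[str, str] = {}
        offenders: list[str] = []
        for rec, val in zip(self.records, values):
            if val in seen:
                offenders.append(f"{seen[val]!r}/{rec.guide_id!r} share {what} {val!r}")
            else:
                seen[val] = rec.guide_id
        if offenders:
            raise LibraryValidationError(
                f"duplicate {what} in library: " + "; ".join(offenders)
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, guide_id: str) -> GuideRecord:
        return self._by_id[guide_id]

    def __contains__(self, guide_id: str) -> bool:
        return guide_id in self._by_id

    @property
    def guide_ids(self) -> list[str]:
        return [r.guide_id for r in self.records]

    @property
    def targeting_genes(self) -> list[str]:
        """Gene symbols with at least one targeting guide, in first-seen order."""
        return [g for g in self.gene_index if g != CONTROL_GENE]

    def guides_for(self, gene: str) -> list[str]:
        return list(self.gene_index.get(gene, []))

    def max_guide_length(self) -> int:
        return max(len(r.sequence) for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": [r.guide_id for r in self.records],
                "gene": [r.gene for r in self.records],
                "sequence": [r.sequence for r in self.records],
                "guide_class": [r.guide_class for r in self.records],
            }
        )


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    genotype: str
    replicate: str
    timepoint_days: float

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise FormatError(
                f"sample {self.sample_id!r}: genotype {self.genotype!r} "
                f"not one of {GENOTYPES}"
            )
        if self.timepoint_days < 0:
            raise FormatError(
                f"sample {self.sample_id!r}: negative timepoint {self.timepoint_days}"
            )


class SampleSheet:
    """Sample metadata: genotype, replicate line, timepoint per sample."""

    def __init__(self, records: Iterable[SampleRecord]):
        self.records = list(records)
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise FormatError(f"duplicate sample_id(s): {dupes}")
        plasmids = [r for r in self.records if r.genotype == "plasmid"]
        if len(plasmids) != 1:
            raise FormatError(
                f"expected exactly one plasmid reference sample, found {len(plasmids)}"
            )
        for geno in ("knockout", "wildtype"):
            reps = [r.replicate for r in self.records if r.genotype == geno]
            if len(set(reps)) != len(reps):
                raise FormatError(f"replicate labels not unique within {geno!r}")
        self._by_id = {r.sample_id: r for r in self.records}

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, sample_id: str) -> SampleRecord:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def plasmid_sample(self) -> str:
        return next(r.sample_id for r in self.records if r.genotype == "plasmid")

    def samples_of(self, genotype: str) -> list[str]:
        return [r.sample_id for r in self.records if r.genotype == genotype]

    def genotype_of(self, sample_id: str) -> str:
        return self._by_id[sample_id].genotype

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "genotype": [r.genotype for r in self.records],
                "replicate": [r.replicate for r in self.records],
                "timepoint_days": [r.timepoint_days for r in self.records],
            }
        )


class CountMatrix:
    """Integer read counts, guides x samples.

    ``depth`` is always the per-sample column sum of matched reads;
    ``unmatched`` tracks reads matching no guide (informational).
    """

    def __init__(
        self,
        guide_ids: Sequence[str],
        sample_ids: Sequence[str],
        counts: np.ndarray,
        unmatched: Mapping[str, int] | None = None,
    ):
        counts = np.asarray(counts)
        if counts.shape != (len(guide_ids), len(sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(guide_ids)} guides x {len(sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at guide {guide_ids[bad[0]]!r}, "
                f"sample {sample_ids[bad[1]]!r}"
            )
        self.guide_ids = list(guide_ids)
        self.sample_ids = list(sample_ids)
        self.counts = counts.astype(np.int64)
        self.unmatched = dict(unmatched) if unmatched else {s: 0 for s in sample_ids}
        self._gidx = {g: i for i, g in enumerate(self.guide_ids)}
        self._sidx = {s: i for i, s in enumerate(self.sample_ids)}
        if len(self._gidx) != len(self.guide_ids):
            raise ValueError("duplicate guide_ids in count matrix")
        if len(self._sidx) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids in count matrix")

    @property
    def depth(self) -> dict[str, int]:
        sums = self.counts.sum(axis=0)
        return {s: int(sums[i]) for i, s in enumerate(self.sample_ids)}

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self._sidx[sample_id]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.guide_ids, name="guide_id"),
            columns=self.sample_ids,
        )

    def reconcile(self, library: GuideLibrary) -> "CountMatrix":
        """Reindex onto the library's guide order, zero-filling absent guides.

        Guides present here but absent from the library are an error; use
        :func:`validate_inputs` to report them first.
        """
        extra = sorted(set(self.guide_ids) - set(library.guide_ids))
        if extra:
            raise ValueError(f"guides absent from library: {extra[:10]}")
        df = self.to_frame().reindex(library.guide_ids, fill_value=0)
        return CountMatrix(
            library.guide_ids, self.sample_ids, df.to_numpy(), self.unmatched
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.guide_ids == other.guide_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class ReferenceGeneSets:
    """Training gene sets for the essentiality classifier."""

    essential: frozenset[str]
    nonessential: frozenset[str]

    def __post_init__(self) -> None:
        if not self.essential or not self.nonessential:
            raise ValueError("reference gene sets must both be non-empty")
        overlap = self.essential & self.nonessential
        if overlap:
            raise ValueError(
                f"reference sets overlap: {sorted(overlap)[:10]}"
            )

    def restrict_to(self, genes: Iterable[str]) -> "ReferenceGeneSets":
        universe = frozenset(genes)
        return ReferenceGeneSets(
            essential=self.essential & universe,
            nonessential=self.nonessential & universe,
        )


# ---------------------------------------------------------------------------
# I/O


def read_library(path: str | Path) -> GuideLibrary:
    """Parse a library TSV into a validated :class:`GuideLibrary`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"guide_id", "gene", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if "guide_class" not in df.columns:
        df["guide_class"] = "targeting"
    df["guide_class"] = df["guide_class"].fillna("targeting")
    records = [
        GuideRecord(
            guide_id=row.guide_id,
            gene=row.gene,
            sequence=row.sequence,
            guide_class=row.guide_class,
        )
        for row in df.itertuples()
    ]
    return GuideLibrary(records)


def write_library(library: GuideLibrary, path: str | Path) -> None:
    library.to_frame().to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, library: GuideLibrary | None = None) -> CountMatrix:
    """Parse a count TSV; with ``library``, zero-fill guides it lacks."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"guide_id": str})
    if "guide_id" not in df.columns:
        raise FormatError(f"{path}: missing guide_id column")
    df = df.set_index("guide_id")
    values = df.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.integer):
        raise ValueError(f"{path}: counts must be integers")
    if values.size and (values < 0).any():
        raise ValueError(f"{path}: negative counts present")
    cm = CountMatrix(list(df.index), list(df.columns), values)
    if library is not None:
        cm = cm.reconcile(library)
    return cm


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "genotype", "replicate", "timepoint_days"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return SampleSheet(
        SampleRecord(
            sample_id=row.sample_id,
            genotype=row.genotype,
            replicate=row.replicate,
            timepoint_days=float(row.timepoint_days),
        )
        for row in df.itertuples()
    )


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> frozenset[str]:
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    return frozenset(genes)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# Cross-input validation


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "fatal" | "warning"
    code: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def fatal(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "fatal"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.fatal

    def raise_if_fatal(self) -> None:
        if self.fatal:
            msgs = "; ".join(i.message for i in self.fatal)
            raise ValueError(f"fatal validation issues: {msgs}")


def validate_inputs(
    library: GuideLibrary,
    counts: CountMatrix | None = None,
    sheet: SampleSheet | None = None,
    refsets: ReferenceGeneSets | None = None,
) -> ValidationReport:
    """Cross-check the four inputs; deterministic and order-independent.

    Fatal: counts contain guides not in the library, or samples not in the
    sheet (analysis cannot proceed).  Warning: reference genes absent from
    the library (they are silently dropped from training downstream).
    """
    report = ValidationReport()
    lib_guides = set(library.guide_ids)
    lib_genes = set(library.gene_index)
    if counts is not None:
        extra_guides = sorted(set(counts.guide_ids) - lib_guides)
        if extra_guides:
            report.issues.append(
                ValidationIssue(
                    "fatal",
                    "unknown_guides",
                    f"{len(extra_guides)} guide(s) in counts absent from "
                    f"library, e.g. {extra_guides[:5]}",
                )
            )
        if sheet is not None:
            extra_samples = sorted(set(counts.sample_ids) - set(sheet.sample_ids))
            if extra_samples:
                report.issues.append(
                    ValidationIssue(
                        "fatal",
                        "unknown_samples",
                        f"sample(s) in counts absent from sheet: {extra_samples}",
                    )
                )
    if refsets is not None:
        for name, genes in (
            ("essential", refsets.essential),
            ("nonessential", refsets.nonessential),
        ):
            dropped = sorted(genes - lib_genes)
            if dropped:
                report.issues.append(
                    ValidationIssue(
                        "warning",
                        f"refset_{name}_not_in_library",
                        f"{len(dropped)} {name} reference gene(s) absent from "
                        f"library and dropped from training, e.g. {dropped[:5]}",
                    )
                )
    return report
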