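"""96-context SNV catalogs.

Somatic single-base substitutions are classified into the standard 96
strand-collapsed categories (6 pyrimidine-reference substitution classes x
16 flanking-base combinations, rendered ``A[C>T]G``). Purine-reference
mutations are reverse-complemented before classification, so the catalog is
invariant to the strand on which a variant was reported.

Coordinates: mutations are 1-based (VCF convention); all interval types are
0-based half-open (BED convention). The conversion happens exactly once, at
the point where a mutation is tested against a region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

#: Fixed 96-category order: substitution class major, then 5' flank, then 3'
#: flank, both lexicographic — the order published COSMIC matrices use.
CATEGORIES_96 = tuple(
    f"{f5}[{sub}]{f3}"
    for sub in SUBSTITUTION_CLASSES
    for f5 in BASES
    for f3 in BASES
)

#: The 32 pyrimidine-centered trinucleotide context classes (alt-allele
#: independent); used as the opportunity space for regional normalization.
CONTEXT_CLASSES_32 = tuple(
    f"{f5}{c}{f3}" for c in ("C", "T") for f5 in BASES for f3 in BASES
)

_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES_96)}
_CTX_INDEX = {c: i for i, c in enumerate(CONTEXT_CLASSES_32)}


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class ReferenceMismatchError(ValueError):
    """Raised when a trinucleotide context disagrees with a mutation's ref."""


@dataclass
class Mutation:
    """One somatic SNV.

    ``pos`` is 1-based. ``vaf`` is the alternate allele fraction, or None
    when not available (e.g. low-coverage calls without depth annotation).
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-ACGT allele {self.ref}>{self.alt}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass
class RegionSet:
    """A named set of genomic intervals, 0-based half-open, merged per chrom."""

    name: str
    intervals: dict = field(default_factory=dict)  # chrom -> (n,2) int array

    @classmethod
    def from_intervals(
        cls, name: str, intervals: Iterable[tuple[str, int, int]]
    ) -> "RegionSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"interval end <= start: {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        merged = {}
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            out: list[list[int]] = []
            for s, e in ivals:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = np.asarray(out, dtype=np.int64)
        return cls(name=name, intervals=merged)

    @classmethod
    def from_bed(cls, path, name: str | None = None) -> "RegionSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                rows.append((parts[0], int(parts[1]), int(parts[2])))
        return cls.from_intervals(name or str(path), rows)

    def extend(self, pad: int) -> "RegionSet":
        """Pad every interval by ``pad`` bp on both sides (floored at 0)."""
        out = [
            (chrom, max(0, int(s) - pad), int(e) + pad)
            for chrom, arr in self.intervals.items()
            for s, e in arr
        ]
        return RegionSet.from_intervals(self.name, out)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position (converted internally to 0-based)."""
        arr = self.intervals.get(chrom)
        if arr is None or len(arr) == 0:
            return False
        p = pos - 1
        i = int(np.searchsorted(arr[:, 0], p, side="right")) - 1
        return i >= 0 and p < arr[i, 1]

    def total_bp(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.intervals.values())
        )

    def iter_intervals(self):
        for chrom in sorted(self.intervals):
            for s, e in self.intervals[chrom]:
                yield chrom, int(s), int(e)


def classify_snv(mut: Mutation, context: str) -> str | None:
    """Classify a mutation into its 96-category label.

    ``context`` is the reference 3-mer centered on the mutated position;
    its middle base must equal ``mut.ref``. Purine-reference mutations are
    reverse-complemented (flanks swap and complement) onto the pyrimidine
    strand. Returns None (unclassifiable) when the context contains an
    ambiguous base.
    """
    context = context.upper()
    if len(context) != 3:
        raise ValueError(f"context must be a 3-mer, got {context!r}")
    if context[1] != mut.ref:
        raise ReferenceMismatchError(
            f"context middle base {context[1]} != ref {mut.ref} "
            f"at {mut.chrom}:{mut.pos}"
        )
    if "N" in context or mut.alt == "N":
        return None
    ref, alt = mut.ref, mut.alt
    if ref in ("A", "G"):
        context = reverse_complement(context)
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def context_class(context: str) -> str | None:
    """Collapse a reference 3-mer to its pyrimidine-centered context class."""
    context = context.upper()
    if "N" in context or len(context) != 3:
        return None
    if context[1] in ("A", "G"):
        context = reverse_complement(context)
    return context


def pyrimidine_strand(ref: str) -> int:
    """+1 if the reported ref allele is the pyrimidine (plus strand), else -1."""
    return 1 if ref in ("C", "T") else -1


def filter_immune_regions(
    muts: Sequence[Mutation], immune: RegionSet
) -> list[Mutation]:
    """Drop mutations inside immune hypermutated loci.

    The interval set is expected to carry any flanking extension already
    (the study pads each locus by 50 kb; use :meth:`RegionSet.extend`).
    Input order is preserved.
    """
    return [m for m in muts if not immune.contains(m.chrom, m.pos)]


def filter_clonal(muts: Sequence[Mutation], vaf_min: float = 0.9) -> list[Mutation]:
    """Retain clonal mutations: strictly vaf > vaf_min."""
    for m in muts:
        if m.vaf is None:
            raise ValueError(
                f"missing VAF for sample {m.sample_id} at {m.chrom}:{m.pos}"
            )
    return [m for m in muts if m.vaf > vaf_min]


def _context_from_reference(reference, chrom: str, pos: int) -> str:
    """Reference 3-mer around a 1-based position; 'N'-padded at contig edges."""
    seq = reference[chrom]
    s = str(seq[max(0, pos - 2) : pos + 1]).upper()
    if pos == 1:
        s = "N" + s
    if len(s) < 3:
        s = s + "N" * (3 - len(s))
    return s


def build_catalog(
    muts: Sequence[Mutation],
    reference: Mapping[str, str],
    restrict_to: RegionSet | None = None,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build the samples x 96 category count matrix.

    ``reference`` is any mapping from chrom to an indexable sequence
    (a dict of strings or a ``pyfaidx.Fasta``). With ``samples`` given, the
    result has one row per roster entry (all-zero rows allowed); otherwise
    rows cover the samples observed among retained mutations.
    Mutations with N in context are dropped and counted in a logged tally.
    """
    missing = sorted({m.chrom for m in muts if m.chrom not in reference})
    if missing:
        raise KeyError(f"chromosomes absent from reference: {missing}")
    counts: dict[str, np.ndarray] = {}
    if samples is not None:
        for s in samples:
            counts[s] = np.zeros(96, dtype=np.int64)
    n_dropped = 0
    for m in muts:
        if restrict_to is not None and not restrict_to.contains(m.chrom, m.pos):
            continue
        cat = classify_snv(m, _context_from_reference(reference, m.chrom, m.pos))
        if cat is None:
            n_dropped += 1
            continue
        row = counts.setdefault(m.sample_id, np.zeros(96, dtype=np.int64))
        row[_CAT_INDEX[cat]] += 1
    if n_dropped:
        logger.info("dropped %d mutations with ambiguous context", n_dropped)
    index = list(samples) if samples is not None else sorted(counts)
    mat = np.vstack([counts[s] for s in index]) if index else np.zeros((0, 96), int)
    return pd.DataFrame(mat, index=pd.Index(index, name="sample_id"),
                        columns=list(CATEGORIES_96))


def read_vcf(path, sample_id: str | None = None) -> list[Mutation]:
    """Read somatic SNVs from a (single-sample) VCF.

    Multi-allelic records contribute one mutation per SNV alt. The VAF is
    taken from FORMAT/AF when present, else INFO/AF, else left missing.
    ``sample_id`` overrides the VCF sample name.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    default_sid = sample_id or (vcf.samples[0] if vcf.samples else "sample")
    muts: list[Mutation] = []
    for var in vcf:
        for alt in var.ALT:
            if len(var.REF) != 1 or len(alt) != 1:
                continue
            if var.REF not in BASES or alt not in BASES:
                continue
            vaf = None
            try:
                af = var.format("AF")
                if af is not None:
                    vaf = float(af[0][0])
            except (KeyError, TypeError):
                pass
            if vaf is None:
                info_af = var.INFO.get("AF")
                if info_af is not None:
                    vaf = float(info_af)
            muts.append(Mutation(default_sid, var.CHROM, var.POS, var.REF,
                                 alt, vaf=vaf))
    return muts


def write_catalog(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t")


def read_catalog(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
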