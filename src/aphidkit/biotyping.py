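"""Diagnostic-SNP biotyping of cotton-melon aphid marker fragments.

The cotton and cucumber host races of *Aphis gossypii* differ at five
fixed nucleotide sites inside a short mitochondrial fragment spanning
the cytb-16S region.  A fragment is classified by (1) anchoring it on
the forward PCR primer, searched on both strands with a small mismatch
tolerance, (2) reading the bases at the five diagnostic offsets, and
(3) matching the 5-base genotype against the two reference patterns:
T,A,A,T,T for the cotton biotype and C,G,G,C,C for the cucumber
biotype.  Sequences where the primer cannot be found (a failed assay in
the wet lab) and genotypes matching neither pattern are called
``other_species``; an IUPAC ambiguity code at a diagnostic site yields
``ambiguous``.

Coordinates are 0-based half-open internally and 1-based in report
strings.  Sequences are uppercased and RNA ``U`` is normalized to ``T``
before any comparison.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerDefinition",
    "SequenceRecord",
    "BiotypeCall",
    "MarkerLocation",
    "PrimerNotFoundError",
    "TruncatedFragmentError",
    "COTTON",
    "CUCUMBER",
    "OTHER_SPECIES",
    "AMBIGUOUS",
    "default_marker",
    "packaged_reference_fragments",
    "normalize_sequence",
    "reverse_complement",
    "locate_marker",
    "extract_genotype",
    "classify_biotype",
    "classify_record",
    "classify_batch",
    "read_fasta",
]

COTTON = "cotton"
CUCUMBER = "cucumber"
OTHER_SPECIES = "other_species"
AMBIGUOUS = "ambiguous"

_IUPAC = set("ACGTRYSWKMBDHVN")
_UNAMBIGUOUS = set("ACGT")


class PrimerNotFoundError(ValueError):
    """Forward primer absent from both strands: the fragment would not amplify."""


class TruncatedFragmentError(ValueError):
    """Anchored fragment too short to cover the diagnostic sites."""


def normalize_sequence(seq: str) -> str:
    """Uppercase, U->T, and validate against the IUPAC nucleotide alphabet."""
    s = str(seq).upper().replace("U", "T")
    if not s:
        raise ValueError("empty sequence")
    bad = set(s) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class MarkerDefinition:
    """Primers, diagnostic offsets and the two reference genotype patterns.

    ``diagnostic_offsets`` are 0-based positions within the anchored
    fragment (the subsequence starting immediately after the forward
    primer match).  The cotton and cucumber patterns must differ at all
    five sites, which makes the two calls mutually exclusive.
    """

    forward_primer: str
    reverse_primer: str
    diagnostic_offsets: tuple[int, int, int, int, int]
    cotton_pattern: str
    cucumber_pattern: str
    max_primer_mismatches: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward_primer", normalize_sequence(self.forward_primer))
        object.__setattr__(self, "reverse_primer", normalize_sequence(self.reverse_primer))
        object.__setattr__(self, "cotton_pattern", normalize_sequence(self.cotton_pattern))
        object.__setattr__(self, "cucumber_pattern", normalize_sequence(self.cucumber_pattern))
        object.__setattr__(self, "diagnostic_offsets", tuple(int(o) for o in self.diagnostic_offsets))
        if len(self.diagnostic_offsets) != 5:
            raise ValueError("exactly 5 diagnostic offsets required")
        if list(self.diagnostic_offsets) != sorted(set(self.diagnostic_offsets)):
            raise ValueError("diagnostic offsets must be strictly increasing")
        if min(self.diagnostic_offsets) < 0:
            raise ValueError("diagnostic offsets must be non-negative")
        if len(self.cotton_pattern) != 5 or len(self.cucumber_pattern) != 5:
            raise ValueError("genotype patterns must have 5 bases")
        if any(a == b for a, b in zip(self.cotton_pattern, self.cucumber_pattern)):
            raise ValueError("cotton and cucumber patterns must differ at all 5 sites")
        if self.max_primer_mismatches < 0:
            raise ValueError("max_primer_mismatches must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerDefinition":
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            forward_primer=cfg["forward_primer"],
            reverse_primer=cfg["reverse_primer"],
            diagnostic_offsets=tuple(cfg["offsets"]),
            cotton_pattern=cfg["cotton_pattern"],
            cucumber_pattern=cfg["cucumber_pattern"],
            max_primer_mismatches=int(cfg.get("max_primer_mismatches", 2)),
        )

    def to_yaml(self, path: str | Path) -> None:
        cfg = {
            "forward_primer": self.forward_primer,
            "reverse_primer": self.reverse_primer,
            "offsets": list(self.diagnostic_offsets),
            "cotton_pattern": self.cotton_pattern,
            "cucumber_pattern": self.cucumber_pattern,
            "max_primer_mismatches": self.max_primer_mismatches,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)


def default_marker() -> MarkerDefinition:
    """The packaged cytb-16S marker definition (synthetic offsets)."""
    ref = resources.files("aphidkit") / "data" / "marker.yaml"
    with resources.as_file(ref) as path:
        return MarkerDefinition.from_yaml(path)


def packaged_reference_fragments() -> dict[str, str]:
    """The two packaged synthetic reference amplicons, keyed by biotype."""
    ref = resources.files("aphidkit") / "data" / "references.fasta"
    with resources.as_file(ref) as path:
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    return {
        COTTON: records["cotton_reference_synthetic"],
        CUCUMBER: records["cucumber_reference_synthetic"],
    }


@dataclass(frozen=True)
class SequenceRecord:
    """One sequenced individual: id, marker-fragment sequence, field metadata."""

    id: str
    sequence: str
    host: str | None = None
    collection_time: str | None = None
    morph: str | None = None  # "alate" | "apterous"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))


@dataclass(frozen=True)
class MarkerLocation:
    """Anchored fragment plus the map back to input coordinates."""

    fragment: str
    orientation: str  # "forward" | "reverse_complement"
    fragment_start: int  # 0-based start in the oriented sequence
    n_mismatches: int
    source_length: int

    def to_original_coord(self, pos: int) -> int:
        """Map a 0-based fragment position to a 0-based input coordinate."""
        oriented = self.fragment_start + pos
        if self.orientation == "forward":
            return oriented
        return self.source_length - 1 - oriented

    def report_coord(self, pos: int) -> int:
        """1-based input coordinate for reports."""
        return self.to_original_coord(pos) + 1


@dataclass(frozen=True)
class BiotypeCall:
    id: str
    call: str  # cotton | cucumber | other_species | ambiguous
    genotype: str | None
    orientation: str | None
    reason: str


def _best_primer_match(seq: str, primer: str, max_mm: int) -> tuple[int, int] | None:
    """(start, mismatches) of the best primer window, or None.

    Best = fewest mismatches, leftmost on ties; only windows with at
    most ``max_mm`` mismatches qualify.
    """
    k = len(primer)
    best: tuple[int, int] | None = None
    for start in range(0, len(seq) - k + 1):
        mm = sum(1 for a, b in zip(seq[start : start + k], primer) if a != b)
        if mm <= max_mm and (best is None or mm < best[1]):
            best = (start, mm)
            if mm == 0:
                break
    return best


def locate_marker(record: SequenceRecord, marker: MarkerDefinition) -> MarkerLocation:
    """Anchor the fragment on the forward primer, trying both strands.

    Returns the subsequence starting right after the primer match, in
    the orientation where the primer was found.  An exact match on
    either strand beats a mismatched one; the forward strand wins ties.
    Raises :class:`PrimerNotFoundError` when neither strand carries the
    primer within ``max_primer_mismatches`` — downstream this becomes an
    ``other_species`` call.
    """
    seq = record.sequence
    rc = reverse_complement(seq)
    fwd = _best_primer_match(seq, marker.forward_primer, marker.max_primer_mismatches)
    rev = _best_primer_match(rc, marker.forward_primer, marker.max_primer_mismatches)
    if fwd is None and rev is None:
        raise PrimerNotFoundError(
            f"record {record.id!r}: forward primer not found in either orientation "
            f"(<= {marker.max_primer_mismatches} mismatches)"
        )
    if rev is None or (fwd is not None and fwd[1] <= rev[1]):
        start, mm = fwd
        oriented, orientation = seq, "forward"
    else:
        start, mm = rev
        oriented, orientation = rc, "reverse_complement"
    frag_start = start + len(marker.forward_primer)
    return MarkerLocation(
        fragment=oriented[frag_start:],
        orientation=orientation,
        fragment_start=frag_start,
        n_mismatches=mm,
        source_length=len(seq),
    )


def extract_genotype(fragment: str, marker: MarkerDefinition) -> str:
    """Bases at the five diagnostic offsets of an anchored fragment."""
    fragment = normalize_sequence(fragment)
    last = marker.diagnostic_offsets[-1]
    if len(fragment) <= last:
        raise TruncatedFragmentError(
            f"fragment of length {len(fragment)} does not cover diagnostic "
            f"site at offset {last} (1-based position {last + 1})"
        )
    return "".join(fragment[o] for o in marker.diagnostic_offsets)


def classify_biotype(genotype: str, marker: MarkerDefinition) -> str:
    """Map a 5-base genotype to cotton / cucumber / ambiguous / other_species."""
    genotype = normalize_sequence(genotype)
    if len(genotype) != 5:
        raise ValueError(f"genotype must have 5 bases, got {len(genotype)}")
    if set(genotype) - _UNAMBIGUOUS:
        return AMBIGUOUS
    if genotype == marker.cotton_pattern:
        return COTTON
    if genotype == marker.cucumber_pattern:
        return CUCUMBER
    return OTHER_SPECIES


def classify_record(record: SequenceRecord, marker: MarkerDefinition) -> BiotypeCall:
    """Full per-sequence pipeline: anchor, read genotype, classify."""
    try:
        loc = locate_marker(record, marker)
    except PrimerNotFoundError:
        return BiotypeCall(
            id=record.id,
            call=OTHER_SPECIES,
            genotype=None,
            orientation=None,
            reason="forward primer not found (not amplifiable)",
        )
    try:
        genotype = extract_genotype(loc.fragment, marker)
    except TruncatedFragmentError as exc:
        return BiotypeCall(
            id=record.id,
            call=OTHER_SPECIES,
            genotype=None,
            orientation=loc.orientation,
            reason=str(exc),
        )
    call = classify_biotype(genotype, marker)
    reasons = {
        COTTON: "genotype matches cotton pattern",
        CUCUMBER: "genotype matches cucumber pattern",
        AMBIGUOUS: "ambiguity code at a diagnostic site",
        OTHER_SPECIES: "genotype matches neither biotype pattern",
    }
    return BiotypeCall(
        id=record.id,
        call=call,
        genotype=genotype,
        orientation=loc.orientation,
        reason=reasons[call],
    )


def classify_batch(
    records: Iterable[SequenceRecord], marker: MarkerDefinition
) -> list[BiotypeCall]:
    """Classify every record; results depend only on each record itself."""
    calls = [classify_record(r, marker) for r in records]
    counts = Counter(c.call for c in calls)
    logger.info(
        "classified %d records: %s",
        len(calls),
        ", ".join(f"{k}={v}" for k, v in sorted(counts.items())) or "none",
    )
    return calls


def read_fasta(
    path: str | Path,
    metadata: Mapping[str, Mapping[str, str]] | None = None,
) -> list[SequenceRecord]:
    """Read marker fragments from FASTA, attaching optional per-id metadata.

    Raises ``ValueError`` naming the record index on malformed entries
    (empty sequence or non-IUPAC characters).
    """
    records: list[SequenceRecord] = []
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        meta = dict(metadata.get(rec.id, {})) if metadata else {}
        try:
            records.append(
                SequenceRecord(
                    id=rec.id,
                    sequence=str(rec.seq),
                    host=meta.get("host"),
                    collection_time=meta.get("collection_time"),
                    morph=meta.get("morph"),
                )
            )
        except ValueError as exc:
            raise ValueError(f"malformed FASTA record #{idx + 1} ({rec.id!r}): {exc}") from exc
    return records
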