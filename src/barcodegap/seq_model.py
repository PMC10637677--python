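"""Domain types and I/O: labeled alignments, trimming, and exclusion filters.

A :class:`LabeledAlignment` is the universal input of the pipeline: a set of
equal-length nucleotide sequences, each carrying a species label. Two reserved
labels mark sequences that are not species members proper: ``OUTGROUP`` and
``UNIDENTIFIED`` (case-insensitive in input files, stored uppercased).

Sequences are normalized at construction: uppercased, ``U`` mapped to ``T``,
and IUPAC ambiguity codes other than ``N`` collapsed to ``N``, so downstream
code only ever sees the closed alphabet ``{A, C, G, T, N, -}``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, BoundsError, EmptyDatasetError, LabelError

OUTGROUP = "OUTGROUP"
UNIDENTIFIED = "UNIDENTIFIED"
RESERVED_LABELS = frozenset({OUTGROUP, UNIDENTIFIED})

ALPHABET = frozenset("ACGTN-")

# IUPAC ambiguity codes (everything except the four bases, N and gap) all
# collapse to N; U is RNA thymine.
_IUPAC_TO_N = str.maketrans(
    {c: "N" for c in "RYSWKMBDHV"} | {"U": "T"}
)


def normalize_sequence(seq: str, seq_id: str = "?") -> str:
    """Uppercase, map U->T and non-N ambiguity codes to N; reject junk."""
    s = seq.upper().translate(_IUPAC_TO_N)
    bad = set(s) - ALPHABET
    if bad:
        raise AlignmentError(
            f"sequence {seq_id!r} contains non-nucleotide characters: "
            f"{sorted(bad)}"
        )
    return s


def _normalize_label(label: str) -> str:
    stripped = label.strip()
    if stripped.upper() in RESERVED_LABELS:
        return stripped.upper()
    return stripped


@dataclass(frozen=True)
class LabeledAlignment:
    """Equal-length sequences with unique ids and per-sequence species labels.

    Parameters
    ----------
    ids
        Unique sequence identifiers, one per sequence.
    seqs
        Aligned nucleotide strings over ``{A,C,G,T,N,-}``, all of the same
        length.
    labels
        Species name per sequence, or the reserved tokens ``OUTGROUP`` /
        ``UNIDENTIFIED``.
    locus
        Free-text tag for the marker (e.g. ``"COI"``, ``"ITS2"``).
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    labels: tuple[str, ...]
    locus: str = ""

    def __init__(
        self,
        ids: Iterable[str],
        seqs: Iterable[str],
        labels: Iterable[str],
        locus: str = "",
    ):
        ids = tuple(ids)
        labels = tuple(_normalize_label(l) for l in labels)
        seqs = tuple(
            normalize_sequence(s, i) for s, i in zip(seqs, ids, strict=False)
        )
        if not (len(ids) == len(seqs) == len(labels)):
            raise AlignmentError(
                f"ids/seqs/labels length mismatch: "
                f"{len(ids)}/{len(seqs)}/{len(labels)}"
            )
        if len(ids) == 0:
            raise EmptyDatasetError("alignment contains no sequences")
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise LabelError(f"duplicate sequence ids: {dupes}")
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            by_len: dict[int, list[str]] = {}
            for i, s in zip(ids, seqs):
                by_len.setdefault(len(s), []).append(i)
            raise AlignmentError(
                f"sequences have unequal lengths {sorted(lengths)}; "
                f"offending ids by length: {by_len}"
            )
        if lengths == {0}:
            raise AlignmentError("alignment length is zero")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "seqs", seqs)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "locus", locus)

    @property
    def n(self) -> int:
        """Number of sequences."""
        return len(self.ids)

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.seqs[0])

    def species_counts(self, include_reserved: bool = False) -> Counter:
        """Count sequences per species label."""
        labels = (
            self.labels
            if include_reserved
            else [l for l in self.labels if l not in RESERVED_LABELS]
        )
        return Counter(labels)

    def subset(self, indices: Sequence[int]) -> "LabeledAlignment":
        """New alignment restricted to the given sequence indices (in order)."""
        if len(indices) == 0:
            raise EmptyDatasetError("subset selects no sequences")
        return LabeledAlignment(
            ids=[self.ids[i] for i in indices],
            seqs=[self.seqs[i] for i in indices],
            labels=[self.labels[i] for i in indices],
            locus=self.locus,
        )


@dataclass(frozen=True)
class FilterPolicy:
    """Which sequence classes to exclude before gap analysis.

    Singleton status is decided *after* unidentified/outgroup removal: a
    species with one sequence left at that point is a singleton.
    """

    drop_unidentified: bool = True
    drop_outgroups: bool = True
    drop_singletons: bool = True


@dataclass
class FilterLog:
    """Itemized record of every sequence an :func:`apply_filter` call removed."""

    unidentified: list[str] = field(default_factory=list)
    outgroups: list[str] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.unidentified) + len(self.outgroups) + len(self.singletons)


def read_labeled_fasta(
    fasta_path: str | Path, labels_path: str | Path, locus: str = ""
) -> LabeledAlignment:
    """Read an aligned FASTA plus a two-column TSV label map.

    The label file must have a header line ``id<TAB>species``. Every FASTA
    record id must appear exactly once in the table (extra table rows are
    tolerated and ignored).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise EmptyDatasetError(f"no FASTA records in {fasta_path}")
    label_map = read_label_table(labels_path)
    ids, seqs, labels = [], [], []
    missing = []
    for rec in records:
        if rec.id not in label_map:
            missing.append(rec.id)
            continue
        ids.append(rec.id)
        seqs.append(str(rec.seq))
        labels.append(label_map[rec.id])
    if missing:
        raise LabelError(
            f"{len(missing)} FASTA ids missing from label table "
            f"{labels_path}: {missing[:10]}"
        )
    return LabeledAlignment(ids=ids, seqs=seqs, labels=labels, locus=locus)


def read_label_table(labels_path: str | Path) -> dict[str, str]:
    """Parse the id->species TSV (header ``id\\tspecies`` required)."""
    label_map: dict[str, str] = {}
    with open(labels_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header[:2]] != ["id", "species"]:
            raise LabelError(
                f"label table {labels_path} must start with header "
                f"'id<TAB>species', got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise LabelError(
                    f"{labels_path}:{lineno}: expected 'id<TAB>species', "
                    f"got {line!r}"
                )
            seq_id = parts[0].strip()
            if seq_id in label_map:
                raise LabelError(f"{labels_path}: duplicate id {seq_id!r}")
            label_map[seq_id] = _normalize_label(parts[1])
    if not label_map:
        raise LabelError(f"label table {labels_path} has no data rows")
    return label_map


def write_labeled_fasta(
    aln: LabeledAlignment,
    fasta_path: str | Path,
    labels_path: str | Path,
    wrap: int = 70,
) -> None:
    """Write FASTA + label TSV that :func:`read_labeled_fasta` round-trips."""
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(aln.ids, aln.seqs)
    ]
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for start in range(0, len(s), wrap):
                fh.write(s[start : start + wrap] + "\n")
    with open(labels_path, "w") as fh:
        fh.write("id\tspecies\n")
        for i, l in zip(aln.ids, aln.labels):
            fh.write(f"{i}\t{l}\n")


def trim_alignment(
    aln: LabeledAlignment, start_col: int, end_col: int
) -> LabeledAlignment:
    """Restrict the alignment to columns [start_col, end_col], 1-based inclusive."""
    if not (1 <= start_col <= end_col <= aln.length):
        raise BoundsError(
            f"trim window [{start_col}, {end_col}] invalid for alignment "
            f"of length {aln.length} (need 1 <= start <= end <= L)"
        )
    return replace(
        aln, seqs=tuple(s[start_col - 1 : end_col] for s in aln.seqs)
    )


def apply_filter(
    aln: LabeledAlignment, policy: FilterPolicy
) -> tuple[LabeledAlignment, FilterLog]:
    """Drop unidentified/outgroup/singleton sequences per policy.

    Order of operations: unidentified and outgroup sequences are removed
    first; singleton species are then determined on what remains. Input
    order is preserved. Raises :class:`EmptyDatasetError` if nothing
    survives.
    """
    log = FilterLog()
    kept: list[int] = []
    for i, label in enumerate(aln.labels):
        if policy.drop_unidentified and label == UNIDENTIFIED:
            log.unidentified.append(aln.ids[i])
        elif policy.drop_outgroups and label == OUTGROUP:
            log.outgroups.append(aln.ids[i])
        else:
            kept.append(i)
    if policy.drop_singletons:
        counts = Counter(aln.labels[i] for i in kept)
        kept2 = []
        for i in kept:
            if aln.labels[i] not in RESERVED_LABELS and counts[aln.labels[i]] == 1:
                log.singletons.append(aln.ids[i])
            else:
                kept2.append(i)
        kept = kept2
    if not kept:
        raise EmptyDatasetError(
            f"filter removed all {aln.n} sequences "
            f"(unidentified={len(log.unidentified)}, "
            f"outgroups={len(log.outgroups)}, singletons={len(log.singletons)})"
        )
    return aln.subset(kept), log
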