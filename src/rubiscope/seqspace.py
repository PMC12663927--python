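"""Aligned-sequence data model and identity-based sequence-space operations.

The rubisco analyses all run on a single multiple sequence alignment of
large-subunit protein sequences.  This module provides the in-memory
container for that alignment plus the primitives built on it: Hamming
identity between aligned rows, removal of gap-dominated columns, greedy
centroid clustering at an identity threshold, and the diversity-coverage
metric (the fraction of cluster representatives that lie within a given
identity of any kinetically characterized variant).

Identity convention
-------------------
Identity between two aligned rows is computed per column:

* columns where *both* rows carry a gap are excluded from the comparison;
* a gap aligned against a residue counts as a mismatch;
* the ambiguity code ``X`` matches nothing (not even another ``X``).

With this convention ``identity(a, a) == 1`` for any gapped,
unambiguous row, and identity is symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
AMBIGUOUS = "X"
ALPHABET = AMINO_ACIDS + GAP + AMBIGUOUS

FORMS = ("I", "I'", "II", "II/III", "III", "unknown")

# integer codes used by the vectorised identity kernel
_GAP_CODE = 0
_X_CODE = len(AMINO_ACIDS) + 1
_CODE = {GAP: _GAP_CODE, AMBIGUOUS: _X_CODE}
_CODE.update({aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)})
_DECODE = {v: k for k, v in _CODE.items()}


class RaggedAlignmentError(ValueError):
    """Raised when input records do not all share the same aligned length."""


@dataclass
class AlignedSeqSet:
    """A protein multiple sequence alignment with per-sequence metadata.

    Parameters
    ----------
    ids
        Unique sequence identifiers, one per row.
    rows
        Equal-length aligned strings over the 20 amino acids, the gap
        character ``-`` and the ambiguity code ``X``.
    form
        Rubisco form label per sequence, one of ``I, I', II, II/III,
        III, unknown``.
    characterized
        Whether a carboxylation rate has been measured for the variant.
    complete
        Whether the sequence is complete (as opposed to a partial ORF).
    column_map
        After column trimming, maps current column index to the column's
        index in the original alignment.  ``None`` for untrimmed sets.
    """

    ids: list[str]
    rows: list[str]
    form: list[str] = field(default_factory=list)
    characterized: list[bool] = field(default_factory=list)
    complete: list[bool] = field(default_factory=list)
    column_map: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.form:
            self.form = ["unknown"] * len(self.ids)
        if not self.characterized:
            self.characterized = [False] * len(self.ids)
        if not self.complete:
            self.complete = [True] * len(self.ids)
        self.validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        """Alignment length (number of columns)."""
        return len(self.rows[0]) if self.rows else 0

    def validate(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            for k, r in enumerate(self.rows):
                if len(r) != len(self.rows[0]):
                    raise RaggedAlignmentError(
                        f"record {self.ids[k]!r} has length {len(r)}, "
                        f"expected {len(self.rows[0])}"
                    )
        for name in ("form", "characterized", "complete"):
            if len(getattr(self, name)) != len(self.ids):
                raise ValueError(f"metadata field {name!r} length mismatch")
        if self.column_map is not None:
            cm = self.column_map
            if len(cm) != self.length:
                raise ValueError("column_map length != alignment length")
            if any(b <= a for a, b in zip(cm, cm[1:])):
                raise ValueError("column_map must be strictly increasing")

    def index_of(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def subset(self, indices: Sequence[int]) -> "AlignedSeqSet":
        """Row subset preserving order of ``indices``."""
        idx = list(indices)
        return AlignedSeqSet(
            ids=[self.ids[i] for i in idx],
            rows=[self.rows[i] for i in idx],
            form=[self.form[i] for i in idx],
            characterized=[self.characterized[i] for i in idx],
            complete=[self.complete[i] for i in idx],
            column_map=list(self.column_map) if self.column_map else None,
        )

    def subset_ids(self, seq_ids: Iterable[str]) -> "AlignedSeqSet":
        return self.subset([self.index_of(s) for s in seq_ids])

    def encoded(self) -> np.ndarray:
        """Integer-coded alignment, shape (n, L); gap=0, X=21, residues 1..20."""
        arr = np.empty((len(self), self.length), dtype=np.int8)
        table = np.full(128, -1, dtype=np.int8)
        for ch, code in _CODE.items():
            table[ord(ch)] = code
        for i, row in enumerate(self.rows):
            codes = table[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
            if (codes < 0).any():
                bad = row[int(np.argmax(codes < 0))]
                raise ValueError(
                    f"record {self.ids[i]!r} has invalid character {bad!r}"
                )
            arr[i] = codes
        return arr

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "form": self.form,
                "characterized": self.characterized,
                "complete": self.complete,
            }
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_alignment(
    path: str | Path, metadata: pd.DataFrame | str | Path | None = None
) -> AlignedSeqSet:
    """Read an aligned FASTA file, optionally joining per-sequence metadata.

    ``metadata`` may be a TSV path or a DataFrame with columns
    ``id, form, characterized, complete``.  Metadata rows whose id does
    not occur in the FASTA are ignored but reported via the returned
    set's ``unmatched_metadata_ids`` attribute.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    rows = [str(r.seq).upper() for r in records]
    aln = AlignedSeqSet(ids=ids, rows=rows)
    unmatched: list[str] = []
    if metadata is not None:
        if not isinstance(metadata, pd.DataFrame):
            metadata = pd.read_csv(metadata, sep="\t", dtype={"id": str})
        meta = metadata.set_index("id")
        unmatched = [m for m in meta.index if m not in set(ids)]
        for i, sid in enumerate(ids):
            if sid in meta.index:
                rec = meta.loc[sid]
                aln.form[i] = str(rec.get("form", "unknown"))
                aln.characterized[i] = bool(rec.get("characterized", False))
                aln.complete[i] = bool(rec.get("complete", True))
    aln.unmatched_metadata_ids = unmatched  # type: ignore[attr-defined]
    return aln


def write_alignment(aln: AlignedSeqSet, path: str | Path, wrap: int = 60) -> None:
    """Write the alignment as FASTA (gap ``-``, lines wrapped at 60)."""
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def write_metadata(aln: AlignedSeqSet, path: str | Path) -> None:
    aln.metadata_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering and trimming
# ---------------------------------------------------------------------------

def length_filter(
    seqs: Mapping[str, str] | AlignedSeqSet,
    min_len: int = 300,
    max_len: int = 700,
) -> tuple[list[str], pd.DataFrame]:
    """Keep sequences whose ungapped length is within [min_len, max_len].

    Bounds are inclusive: the selection removes sequences *shorter than*
    ``min_len`` or *longer than* ``max_len``.  Returns the kept ids and a
    rejection report (id, length, reason).
    """
    if isinstance(seqs, AlignedSeqSet):
        items = list(zip(seqs.ids, seqs.rows))
    else:
        items = list(seqs.items())
    kept: list[str] = []
    rejected: list[tuple[str, int, str]] = []
    for sid, seq in items:
        n = len(seq) - seq.count(GAP)
        if n < min_len:
            rejected.append((sid, n, f"shorter than {min_len}"))
        elif n > max_len:
            rejected.append((sid, n, f"longer than {max_len}"))
        else:
            kept.append(sid)
    report = pd.DataFrame(rejected, columns=["id", "length", "reason"])
    return kept, report


def trim_gap_columns(aln: AlignedSeqSet, max_gap_frac: float = 0.95) -> AlignedSeqSet:
    """Drop alignment columns whose gap fraction strictly exceeds the cutoff.

    The default 0.95 removes columns that are >95% gaps; a column at
    exactly the cutoff is kept.  The surviving columns' original indices
    are recorded in ``column_map`` (composed with any existing map).
    Idempotent at a fixed cutoff.
    """
    if not 0 < max_gap_frac <= 1:
        raise ValueError("max_gap_frac must be in (0, 1]")
    arr = aln.encoded()
    gap_frac = (arr == _GAP_CODE).mean(axis=0)
    keep = np.flatnonzero(gap_frac <= max_gap_frac)
    if keep.size == 0:
        raise ValueError("all alignment columns exceed the gap-fraction cutoff")
    prior = aln.column_map or list(range(aln.length))
    new_rows = ["".join(row[j] for j in keep) for row in aln.rows]
    return AlignedSeqSet(
        ids=list(aln.ids),
        rows=new_rows,
        form=list(aln.form),
        characterized=list(aln.characterized),
        complete=list(aln.complete),
        column_map=[prior[j] for j in keep],
    )


# ---------------------------------------------------------------------------
# Identity
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Hamming identity between two aligned rows (see module docstring)."""
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    matches = 0
    compared = 0
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            continue
        compared += 1
        if x == y and x != AMBIGUOUS:
            matches += 1
    if compared == 0:
        raise ValueError("identity undefined: no comparable columns")
    return matches / compared


def identity_matrix(
    aln: AlignedSeqSet, other: AlignedSeqSet | None = None
) -> np.ndarray:
    """All-pairs identity, vectorised.

    With one argument, returns the symmetric (n, n) matrix over the set;
    with two, the (n, m) cross matrix (rows of ``aln`` vs rows of
    ``other``; the two sets must share a coordinate system).
    """
    a = aln.encoded()
    b = a if other is None else other.encoded()
    if b.shape[1] != a.shape[1]:
        raise ValueError("alignments are not in the same coordinate system")
    n, m = a.shape[0], b.shape[0]
    out = np.empty((n, m), dtype=float)
    a_gap = a == _GAP_CODE
    b_gap = b == _GAP_CODE
    a_res = (a != _GAP_CODE) & (a != _X_CODE)
    for i in range(n):
        both_gap = a_gap[i][None, :] & b_gap
        compared = (~both_gap).sum(axis=1)
        match = ((a[i][None, :] == b) & a_res[i][None, :]).sum(axis=1)
        if (compared == 0).any():
            raise ValueError("identity undefined for an all-gap pair")
        out[i] = match / compared
    return out


# ---------------------------------------------------------------------------
# Greedy clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Greedy identity clustering: centroids and their members.

    Every sequence belongs to exactly one cluster; members have identity
    >= threshold to their centroid and centroids have pairwise identity
    < threshold.
    """

    threshold: float
    clusters: list[tuple[str, list[str]]]

    @property
    def centroid_ids(self) -> list[str]:
        return [c for c, _ in self.clusters]

    def assignments(self) -> dict[str, str]:
        out = {}
        for centroid, members in self.clusters:
            out[centroid] = centroid
            for m in members:
                out[m] = centroid
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for centroid, members in self.clusters:
            rows.append((centroid, centroid, True))
            rows.extend((m, centroid, False) for m in members)
        return pd.DataFrame(rows, columns=["id", "centroid", "is_centroid"])


def greedy_cluster(
    aln: AlignedSeqSet, threshold: float, order: str | Sequence[str] = "length"
) -> ClusterSet:
    """Greedy centroid clustering at an identity threshold.

    Sequences are scanned in a deterministic order (``"length"``:
    decreasing ungapped length with lexicographic id tie-break,
    mirroring greedy centroid tools; ``"input"``: file order; or an
    explicit id sequence).  Each sequence joins the first existing
    centroid it matches at >= threshold, else founds a new cluster.
    Thresholds above 1 are clamped to 1.
    """
    if threshold <= 0:
        # every sequence matches the first centroid: a single cluster
        threshold = 0.0
    threshold = min(threshold, 1.0)
    if isinstance(order, str):
        if order == "length":
            key = {
                sid: (-(len(row) - row.count(GAP)), sid)
                for sid, row in zip(aln.ids, aln.rows)
            }
            scan = sorted(aln.ids, key=key.__getitem__)
        elif order == "input":
            scan = list(aln.ids)
        else:
            raise ValueError(f"unknown ordering rule {order!r}")
    else:
        scan = list(order)
        if set(scan) != set(aln.ids):
            raise ValueError("explicit order must be a permutation of the ids")

    sim = identity_matrix(aln)
    pos = {sid: i for i, sid in enumerate(aln.ids)}
    centroids: list[str] = []
    members: dict[str, list[str]] = {}
    for sid in scan:
        i = pos[sid]
        placed = False
        for c in centroids:
            if sim[i, pos[c]] >= threshold:
                members[c].append(sid)
                placed = True
                break
        if not placed:
            centroids.append(sid)
            members[sid] = []
    return ClusterSet(
        threshold=threshold, clusters=[(c, members[c]) for c in centroids]
    )


# ---------------------------------------------------------------------------
# Diversity coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageCurve:
    """Diversity coverage as a function of the identity threshold X.

    ``coverage[i]`` is the fraction of representative sequences sharing
    at least ``thresholds[i]`` identity with any characterized variant.
    Non-increasing in X by construction.
    """

    thresholds: list[float]
    coverage: list[float]
    n_representatives: int
    n_characterized: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "coverage": self.coverage}
        )


DEFAULT_COVERAGE_THRESHOLDS = [round(0.50 + 0.05 * k, 2) for k in range(11)]


def diversity_coverage(
    representatives: AlignedSeqSet,
    characterized: AlignedSeqSet,
    thresholds: Sequence[float] | None = None,
) -> CoverageCurve:
    """Fraction of representatives within identity X of any characterized variant."""
    if thresholds is None:
        thresholds = DEFAULT_COVERAGE_THRESHOLDS
    if len(representatives) == 0:
        raise ValueError("empty representative set")
    if len(characterized) == 0:
        cov = [1.0 if x <= 0 else 0.0 for x in thresholds]
        return CoverageCurve(list(thresholds), cov, len(representatives), 0)
    best = identity_matrix(representatives, characterized).max(axis=1)
    cov = [float((best >= x).mean()) for x in thresholds]
    return CoverageCurve(
        thresholds=list(thresholds),
        coverage=cov,
        n_representatives=len(representatives),
        n_characterized=len(characterized),
    )
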