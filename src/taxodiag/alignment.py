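"""Labelled multiple sequence alignments, region maps and distance primitives.

Sequences are stored exactly as aligned (gap ``-``), case-folded to
uppercase with ``U`` mapped to ``T`` on read. All printed coordinates in
this package are 1-based inclusive; alignment columns are likewise
numbered from 1 in the public API.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from . import iupac

RANKS = ("species", "genus", "family", "order")

#: region names accepted in a RegionMap
REGION_NAMES = ("ITS1", "5.8S", "ITS2", "LSU", "SSU", "full")


class AlignmentError(ValueError):
    """Malformed alignment input (ragged records, illegal characters...)."""


class UndefinedDistanceError(ValueError):
    """No comparable columns between two sequences in the requested region."""


@dataclass
class AlignedSequence:
    accession: str
    residues: str
    taxon_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlignmentError(f"{self.accession}: empty sequence")
        bad = iupac.first_illegal(self.residues)
        if bad is not None:
            raise AlignmentError(
                f"{self.accession}: illegal character {self.residues[bad]!r} "
                f"at column {bad + 1}"
            )

    def label(self, rank: str) -> str | None:
        return self.taxon_labels.get(rank) or None


class Alignment:
    """Ordered collection of equal-length :class:`AlignedSequence`."""

    def __init__(self, members: Iterable[AlignedSequence]):
        self.members: list[AlignedSequence] = list(members)
        if len(self.members) < 2:
            raise AlignmentError("an alignment needs at least 2 sequences")
        self.n_columns = len(self.members[0].residues)
        self._index: dict[str, int] = {}
        for m in self.members:
            if len(m.residues) != self.n_columns:
                raise AlignmentError(
                    f"ragged alignment: {m.accession} has {len(m.residues)} "
                    f"columns, expected {self.n_columns}"
                )
            if m.accession in self._index:
                raise AlignmentError(f"duplicate accession {m.accession}")
            self._index[m.accession] = len(self._index)
        self._encoded: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, accession: str) -> bool:
        return accession in self._index

    @property
    def accessions(self) -> list[str]:
        return [m.accession for m in self.members]

    def get(self, accession: str) -> AlignedSequence:
        try:
            return self.members[self._index[accession]]
        except KeyError:
            raise KeyError(f"accession {accession!r} not in alignment") from None

    def row(self, accession: str) -> int:
        return self._index[accession]

    def encoded(self) -> np.ndarray:
        """(n_members, n_columns) uint8 IUPAC bitmask matrix (gap = 0)."""
        if self._encoded is None:
            self._encoded = np.vstack([iupac.encode(m.residues) for m in self.members])
        return self._encoded

    def members_of(self, name: str, rank: str = "species") -> list[str]:
        """Accessions labelled *name* at *rank*."""
        return [m.accession for m in self.members if m.label(rank) == name]

    def groups(self, rank: str = "species") -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for m in self.members:
            lab = m.label(rank)
            if lab is not None:
                out.setdefault(lab, []).append(m.accession)
        return out

    def unmapped(self) -> list[str]:
        """Accessions with no taxon label at any rank."""
        return [m.accession for m in self.members
                if not any(m.label(r) for r in RANKS)]


@dataclass(frozen=True)
class RegionMap:
    """1-based inclusive alignment-column spans for named rRNA regions."""

    entries: Mapping[str, tuple[int, int]]
    n_columns: int | None = None

    def __post_init__(self) -> None:
        spans = []
        for name, (start, end) in self.entries.items():
            if not 1 <= start <= end:
                raise ValueError(f"region {name}: bad span {start}..{end}")
            if self.n_columns is not None and end > self.n_columns:
                raise ValueError(
                    f"region {name}: end {end} exceeds {self.n_columns} columns"
                )
            if name != "full":
                spans.append((start, end, name))
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"regions {n1} and {n2} overlap")

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def span(self, name: str) -> tuple[int, int]:
        try:
            return self.entries[name]
        except KeyError:
            raise KeyError(f"region {name!r} not defined") from None

    def length(self, name: str) -> int:
        start, end = self.span(name)
        return end - start + 1

    def columns(self, name: str) -> slice:
        """0-based column slice for numpy indexing."""
        start, end = self.span(name)
        return slice(start - 1, end)

    def region_of(self, column: int) -> str | None:
        """Name of the (non-'full') region containing a 1-based column."""
        for name, (start, end) in self.entries.items():
            if name != "full" and start <= column <= end:
                return name
        if "full" in self.entries:
            s, e = self.entries["full"]
            if s <= column <= e:
                return "full"
        return None

    @classmethod
    def from_json(cls, source: str | Path, n_columns: int | None = None) -> "RegionMap":
        data = json.loads(Path(source).read_text())
        return cls({k: (int(v[0]), int(v[1])) for k, v in data.items()}, n_columns)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({k: list(v) for k, v in self.entries.items()}, indent=2) + "\n"
        )


class CoordinateIndex:
    """Bidirectional alignment-column <-> degapped-position maps.

    Positions are 1-based on the degapped sequence; region-relative
    positions count non-gap residues from the region's first column.
    """

    def __init__(self, alignment: Alignment, region_map: RegionMap | None = None):
        self.alignment = alignment
        self.region_map = region_map
        self._col_to_pos: dict[str, np.ndarray] = {}
        self._pos_to_col: dict[str, np.ndarray] = {}
        for m in alignment.members:
            nongap = np.frombuffer(m.residues.encode(), dtype=np.uint8) != ord("-")
            cum = np.cumsum(nongap)
            col_to_pos = np.where(nongap, cum, 0)  # 0 = gap, no image
            self._col_to_pos[m.accession] = col_to_pos
            self._pos_to_col[m.accession] = np.flatnonzero(nongap) + 1

    def degapped_position(self, accession: str, column: int) -> int:
        """1-based degapped position of *column*; raises on a gap."""
        pos = int(self._col_to_pos[accession][column - 1])
        if pos == 0:
            raise ValueError(f"{accession}: column {column} is a gap, no image")
        return pos

    def column_of(self, accession: str, position: int) -> int:
        """Alignment column of the 1-based degapped *position*."""
        return int(self._pos_to_col[accession][position - 1])

    def column_to_region_position(self, accession: str, column: int) -> tuple[str, int]:
        if self.region_map is None:
            raise ValueError("no region map attached")
        region = self.region_map.region_of(column)
        if region is None:
            raise ValueError(f"column {column} falls outside all regions")
        start, _ = self.region_map.span(region)
        arr = self._col_to_pos[accession]
        if arr[column - 1] == 0:
            raise ValueError(f"{accession}: column {column} is a gap, no image")
        before = int(arr[start - 2]) if start > 1 else 0
        return region, int(arr[column - 1]) - before

    def region_position_to_column(self, accession: str, region: str, position: int) -> int:
        if self.region_map is None:
            raise ValueError("no region map attached")
        start, end = self.region_map.span(region)
        arr = self._col_to_pos[accession]
        before = int(arr[start - 2]) if start > 1 else 0
        target = before + position
        cols = np.flatnonzero(arr[start - 1:end] == target)
        if not cols.size:
            raise ValueError(
                f"{accession}: no residue at {region} position {position}"
            )
        return start + int(cols[0])


# ---------------------------------------------------------------------------
# I/O

def read_taxon_map(source: str | Path) -> dict[str, dict[str, str]]:
    """Read an accession -> rank labels table (TSV with header)."""
    out: dict[str, dict[str, str]] = {}
    with open(source, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "accession" not in reader.fieldnames:
            raise AlignmentError("taxon map must have an 'accession' column")
        for row in reader:
            acc = row["accession"].strip()
            out[acc] = {r: row.get(r, "").strip() for r in RANKS if row.get(r, "").strip()}
    return out


def write_taxon_map(path: str | Path, labels: Mapping[str, Mapping[str, str]]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(("accession",) + RANKS)
        for acc, labs in labels.items():
            writer.writerow([acc] + [labs.get(r, "") for r in RANKS])


def read_alignment(fasta_source: str | Path,
                   taxonmap_source: str | Path | None = None) -> Alignment:
    """Read an aligned FASTA plus optional taxon-map TSV.

    The accession is the first whitespace-delimited token of each header.
    Residues are case-folded and ``U`` is mapped to ``T``. Ragged records
    and characters outside the IUPAC alphabet are hard errors.
    """
    labels = read_taxon_map(taxonmap_source) if taxonmap_source else {}
    members = []
    for rec in SeqIO.parse(str(fasta_source), "fasta"):
        acc = rec.id.split()[0]
        seq = iupac.normalize(str(rec.seq))
        members.append(AlignedSequence(acc, seq, dict(labels.get(acc, {}))))
    if not members:
        raise AlignmentError(f"no FASTA records in {fasta_source}")
    return Alignment(members)


def write_alignment(path: str | Path, alignment: Alignment) -> None:
    with open(path, "w") as fh:
        for m in alignment.members:
            fh.write(f">{m.accession}\n{m.residues}\n")


# ---------------------------------------------------------------------------
# Distance

def _long_gap_run_mask(chars: np.ndarray, max_indel: int) -> np.ndarray:
    """Boolean mask of columns inside gap runs longer than *max_indel*."""
    gap = chars == 0
    mask = np.zeros(gap.shape, dtype=bool)
    if not gap.any():
        return mask
    padded = np.concatenate(([False], gap, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start > max_indel:
            mask[start:end] = True
    return mask


def gap_runs(residues: str, max_indel: int = 0) -> list[tuple[int, int]]:
    """(1-based start, length) of gap runs longer than *max_indel*."""
    enc = iupac.encode(residues)
    runs = []
    padded = np.concatenate(([False], enc == 0, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start > max_indel:
            runs.append((int(start) + 1, int(end - start)))
    return runs


def pairwise_distance(a: AlignedSequence, b: AlignedSequence,
                      region: str | None = None,
                      region_map: RegionMap | None = None,
                      gap_policy: str = "count",
                      max_indel: int = 20,
                      ambiguity: str = "lenient",
                      drop_ambiguous: bool = False) -> float:
    """Uncorrected p-distance between two aligned sequences over a region.

    Comparable columns exclude gap-vs-gap sites and every column inside a
    gap run longer than *max_indel* in either sequence (long deletions are
    treated as single events, not stacks of point differences). Under
    ``gap_policy="count"`` a gap opposite a base is one difference,
    representing indels alongside substitutions; ``gap_policy="exclude"``
    drops such columns. Ambiguity codes match leniently when their base
    sets intersect; ``ambiguity="strict"`` requires identical symbols, and
    ``drop_ambiguous=True`` removes any column where either residue is an
    ambiguity code from the comparison altogether.
    """
    ea, eb = iupac.encode(a.residues), iupac.encode(b.residues)
    if region is not None:
        if region_map is None:
            raise ValueError("region given without a region map")
        sl = region_map.columns(region)
        ea, eb = ea[sl], eb[sl]
    excluded = _long_gap_run_mask(ea, max_indel) | _long_gap_run_mask(eb, max_indel)
    gap_a, gap_b = ea == 0, eb == 0
    excluded |= gap_a & gap_b
    if gap_policy == "exclude":
        excluded |= gap_a ^ gap_b
    elif gap_policy != "count":
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    if drop_ambiguous:
        pure = np.isin(ea, (1, 2, 4, 8)) | gap_a
        pure &= np.isin(eb, (1, 2, 4, 8)) | gap_b
        excluded |= ~pure
    comparable = ~excluded
    n = int(comparable.sum())
    if n == 0:
        raise UndefinedDistanceError(
            f"{a.accession} vs {b.accession}: no comparable columns"
        )
    if ambiguity == "lenient":
        match = (ea & eb) != 0
    elif ambiguity == "strict":
        match = (ea == eb) & (ea != 0)
    else:
        raise ValueError(f"unknown ambiguity policy {ambiguity!r}")
    diffs = int((comparable & ~match).sum())
    return diffs / n
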