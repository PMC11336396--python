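"""Diagnostic barcode selection and molecular species diagnoses.

A diagnosis for a target species is a short (20-30 base) window of the
alignment in which the type sequence (the canonical, usually the
lectotype) differs from every non-target sequence by more than it
differs from any conspecific sequence. The usable mismatch allowances
form the integer interval [d_in, d_out - 1], where d_in is the largest
window Hamming distance from the canonical to a conspecific and d_out
the smallest distance to any non-target; the printed allowance is capped
at 1 by convention ("no"/"one mismatch allowed").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import iupac
from .alignment import (
    Alignment,
    CoordinateIndex,
    RegionMap,
    gap_runs,
    pairwise_distance,
)

EN_DASH = "–"

_PURE = (1, 2, 4, 8)


@dataclass(frozen=True)
class WindowSpec:
    """Contiguous alignment window, 1-based start column."""
    start_column: int
    length: int

    @property
    def end_column(self) -> int:
        return self.start_column + self.length - 1

    def overlaps(self, other: "WindowSpec") -> bool:
        return (self.start_column <= other.end_column
                and other.start_column <= self.end_column)


@dataclass
class DistanceProfile:
    d_in: int
    d_out: int
    nearest_out: str
    ambiguous_in_target: int

    @property
    def margin(self) -> int:
        return self.d_out - self.d_in


@dataclass
class Diagnosis:
    target: str
    region: str
    positions: tuple[int, int]         # region-relative, 1-based inclusive
    barcode: str                       # degapped canonical window, lowercase
    allowance_interval: tuple[int, int]
    reported_allowance: int
    margin: int
    canonical: str = ""
    window: WindowSpec | None = None   # alignment columns, for validation

    @property
    def length_consistent(self) -> bool:
        return self.positions[1] - self.positions[0] + 1 == len(self.barcode)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "region": self.region,
            "positions": list(self.positions),
            "barcode": self.barcode,
            "allowance_interval": list(self.allowance_interval),
            "reported_allowance": self.reported_allowance,
            "margin": self.margin,
            "canonical": self.canonical,
            "window": [self.window.start_column, self.window.length]
            if self.window else None,
        }


@dataclass
class RegionFailure:
    """Machine-readable reason a region yielded no diagnosis."""
    region: str
    reason: str
    best_margin: int | None = None


@dataclass
class VariabilityReport:
    taxon: str
    region: str
    max_pairwise: float
    n_sequences: int
    excluded_indel_runs: list[tuple[str, int]] = field(default_factory=list)
    single_sequence: bool = False


@dataclass
class DiagnosisConfig:
    l_min: int = 20
    l_max: int = 30
    min_separation: int = 2
    allowance_cap: int = 1
    rank: str = "species"
    canonical: str | None = None   # default: first target accession
    gap_policy: str = "count"
    max_indel: int = 20


# ---------------------------------------------------------------------------
# Window primitives

def _diff_row(enc_a: np.ndarray, enc_b: np.ndarray) -> np.ndarray:
    """Per-column difference indicator under the window policy.

    Gap-vs-gap is not a difference; gap-vs-base is; two bases differ when
    their IUPAC sets are disjoint.
    """
    both_gap = (enc_a == 0) & (enc_b == 0)
    match = ((enc_a & enc_b) != 0) | both_gap
    return (~match).astype(np.int64)


def hamming_window(aln: Alignment, window: WindowSpec,
                   ref: str, other: str) -> int:
    """Mismatch count between two members over a window."""
    enc = aln.encoded()
    sl = slice(window.start_column - 1, window.end_column)
    return int(_diff_row(enc[aln.row(ref), sl], enc[aln.row(other), sl]).sum())


def enumerate_windows(aln: Alignment, region_map: RegionMap, region: str,
                      l_min: int = 20, l_max: int = 30) -> Iterator[WindowSpec]:
    """All windows of each length in [l_min, l_max] inside a region.

    Ordered by start column, then length. A region shorter than l_min
    yields nothing.
    """
    start, end = region_map.span(region)
    for s in range(start, end + 1):
        for length in range(l_min, l_max + 1):
            if s + length - 1 <= end:
                yield WindowSpec(s, length)


def window_profile(aln: Alignment, window: WindowSpec, target: str,
                   canonical: str | None = None,
                   rank: str = "species") -> DistanceProfile:
    """Exhaustive target-vs-rest distance profile for one window."""
    targets = aln.members_of(target, rank)
    if not targets:
        raise ValueError(f"no members labelled {target!r} at rank {rank}")
    non_targets = [a for a in aln.accessions if a not in set(targets)]
    if not non_targets:
        raise ValueError(f"{target!r} covers the whole alignment")
    canon = canonical or targets[0]
    d_in = max(hamming_window(aln, window, canon, t) for t in targets)
    d_out, nearest = min(
        (hamming_window(aln, window, canon, a), a) for a in non_targets
    )
    sl = slice(window.start_column - 1, window.end_column)
    enc = aln.encoded()
    rows = [aln.row(t) for t in targets]
    sub = enc[rows][:, sl]
    ambiguous = int((~np.isin(sub, _PURE) & (sub != 0)).sum())
    return DistanceProfile(d_in, d_out, nearest, ambiguous)


def mismatch_allowance(profile: DistanceProfile,
                       cap: int = 1) -> tuple[tuple[int, int] | None, int | None]:
    """Valid allowance interval [d_in, d_out-1] and the value to print.

    Empty interval (None) means the window is not diagnostic. The printed
    value is the largest allowance not exceeding *cap*, floored at d_in.
    """
    lo, hi = profile.d_in, profile.d_out - 1
    if lo > hi:
        return None, None
    reported = min(hi, cap)
    if reported < lo:
        reported = lo
    return (lo, hi), reported


# ---------------------------------------------------------------------------
# Search

def _window_stats(diff: np.ndarray, length: int) -> np.ndarray:
    """Sliding-window sums of a (rows, cols) int matrix, every start."""
    cs = np.cumsum(diff, axis=-1)
    cs = np.concatenate([np.zeros(diff.shape[:-1] + (1,), dtype=cs.dtype), cs],
                        axis=-1)
    return cs[..., length:] - cs[..., :-length]


def find_diagnoses(aln: Alignment, target: str, region_map: RegionMap,
                   regions: Sequence[str] | None = None,
                   config: DiagnosisConfig | None = None,
                   ) -> tuple[list[Diagnosis], list[RegionFailure]]:
    """Best diagnostic window per region for a target taxon.

    Windows must be free of ambiguity codes in the target members, keep
    every non-target at distance >= ``min_separation`` from the canonical
    sequence, and admit a non-empty allowance interval. Ranking: widest
    margin (d_out - d_in), then fewest gap columns in the canonical
    window, then leftmost start, then shortest length.
    """
    cfg = config or DiagnosisConfig()
    if regions is None:
        regions = [r for r in region_map.entries if r != "full"]
    targets = aln.members_of(target, cfg.rank)
    if not targets:
        raise ValueError(f"no members labelled {target!r} at rank {cfg.rank}")
    target_set = set(targets)
    non_rows = [i for i, a in enumerate(aln.accessions) if a not in target_set]
    if not non_rows:
        raise ValueError(f"{target!r} covers the whole alignment")
    canon = cfg.canonical or targets[0]
    enc = aln.encoded()
    canon_row = enc[aln.row(canon)]

    diff = np.array([_diff_row(canon_row, enc[i]) for i in range(len(aln))])
    t_rows = [aln.row(t) for t in targets]
    ambig_cols = (~np.isin(enc[t_rows], _PURE) & (enc[t_rows] != 0)).sum(axis=0)
    canon_gap = (canon_row == 0).astype(np.int64)

    index = CoordinateIndex(aln, region_map)
    diagnoses: list[Diagnosis] = []
    failures: list[RegionFailure] = []
    for region in regions:
        r0, r1 = region_map.span(region)
        best = None          # (score tuple, WindowSpec, d_in, d_out)
        best_margin = None
        for length in range(cfg.l_min, cfg.l_max + 1):
            width = r1 - r0 + 1
            if length > width:
                continue
            sl = slice(r0 - 1, r1)
            sums = _window_stats(diff[:, sl], length)       # (n, starts)
            d_in = sums[t_rows].max(axis=0)
            d_out = sums[non_rows].min(axis=0)
            amb = _window_stats(ambig_cols[None, sl], length)[0]
            gaps = _window_stats(canon_gap[None, sl], length)[0]
            margin = d_out - d_in
            mbest = int(margin.max()) if margin.size else None
            if mbest is not None and (best_margin is None or mbest > best_margin):
                best_margin = mbest
            ok = (amb == 0) & (d_out >= cfg.min_separation) & (d_in <= d_out - 1)
            for s in np.flatnonzero(ok):
                score = (-int(margin[s]), int(gaps[s]), r0 + int(s), length)
                if best is None or score < best[0]:
                    best = (score, WindowSpec(r0 + int(s), length),
                            int(d_in[s]), int(d_out[s]))
        if best is None:
            reason = ("region shorter than minimum window"
                      if r1 - r0 + 1 < cfg.l_min else "no separation")
            failures.append(RegionFailure(region, reason, best_margin))
            continue
        _, window, di, do = best
        diagnoses.append(_make_diagnosis(aln, index, region, window, target,
                                         canon, di, do, cfg))
    return diagnoses, failures


def _make_diagnosis(aln: Alignment, index: CoordinateIndex, region: str,
                    window: WindowSpec, target: str, canon: str,
                    d_in: int, d_out: int, cfg: DiagnosisConfig) -> Diagnosis:
    residues = aln.get(canon).residues[window.start_column - 1:window.end_column]
    barcode = residues.replace("-", "").lower()
    cols = [c for c in range(window.start_column, window.end_column + 1)
            if aln.get(canon).residues[c - 1] != "-"]
    _, p0 = index.column_to_region_position(canon, cols[0])
    _, p1 = index.column_to_region_position(canon, cols[-1])
    interval, reported = mismatch_allowance(
        DistanceProfile(d_in, d_out, "", 0), cfg.allowance_cap)
    assert interval is not None
    return Diagnosis(target=target, region=region, positions=(p0, p1),
                     barcode=barcode, allowance_interval=interval,
                     reported_allowance=reported, margin=d_out - d_in,
                     canonical=canon, window=window)


# ---------------------------------------------------------------------------
# Variability & species counts

def within_group_variability(aln: Alignment, taxon: str, region: str,
                             region_map: RegionMap,
                             rank: str = "species",
                             gap_policy: str = "count",
                             max_indel: int = 20) -> VariabilityReport:
    """Maximum pairwise p-distance among a taxon's sequences over a region.

    Long gap runs (> max_indel columns) are excluded from the comparisons,
    as single indel events rather than runs of point differences; the
    excluded runs are listed per accession.
    """
    members = aln.members_of(taxon, rank)
    if not members:
        raise ValueError(f"no members labelled {taxon!r} at rank {rank}")
    sl = region_map.columns(region)
    excluded = []
    for acc in members:
        for start, length in gap_runs(aln.get(acc).residues[sl], max_indel):
            excluded.append((acc, length))
    if len(members) == 1:
        return VariabilityReport(taxon, region, 0.0, 1, excluded,
                                 single_sequence=True)
    best = 0.0
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            d = pairwise_distance(aln.get(a), aln.get(b), region, region_map,
                                  gap_policy=gap_policy, max_indel=max_indel)
            best = max(best, d)
    return VariabilityReport(taxon, region, best, len(members), excluded)


def estimate_species_count(aln: Alignment, genus: str, region: str,
                           region_map: RegionMap, threshold: float = 0.03,
                           rank: str = "genus",
                           **distance_kwargs) -> tuple[int, dict[str, int]]:
    """Approximate species count within a genus by single-linkage clustering.

    Members closer than *threshold* (p-distance over *region*) are chained
    into one cluster; the cluster count approximates the number of
    (potential) species. Returns (count, accession -> cluster id).
    """
    members = aln.members_of(genus, rank)
    if not members:
        raise ValueError(f"no members labelled {genus!r} at rank {rank}")
    if len(members) == 1:
        return 1, {members[0]: 1}
    n = len(members)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_distance(aln.get(members[i]), aln.get(members[j]),
                                  region, region_map, **distance_kwargs)
            dm[i, j] = dm[j, i] = d
    labels = fcluster(linkage(squareform(dm), method="single"),
                      t=threshold, criterion="distance")
    return int(labels.max()), dict(zip(members, (int(x) for x in labels)))


# ---------------------------------------------------------------------------
# Validation

@dataclass
class ValidationReport:
    diagnosis: Diagnosis
    target_within_allowance: bool
    nontarget_beyond_allowance: bool
    length_consistent: bool
    failing_targets: list[tuple[str, int]] = field(default_factory=list)
    failing_nontargets: list[tuple[str, int]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (self.target_within_allowance and self.nontarget_beyond_allowance
                and self.length_consistent)


def validate_diagnosis(aln: Alignment, diagnosis: Diagnosis,
                       region_map: RegionMap,
                       rank: str = "species") -> ValidationReport:
    """Reverse-check a diagnosis against an alignment.

    Verifies that (a) every target sequence matches the barcode within the
    reported allowance, (b) every non-target sequence exceeds it, and
    (c) the printed span length equals the barcode length. Failures are
    enumerated, never corrected.
    """
    bad = iupac.first_illegal(iupac.normalize(diagnosis.barcode))
    if bad is not None:
        raise ValueError(f"barcode contains illegal character at {bad + 1}")
    window = diagnosis.window
    if window is None:
        window = _anchor_window(aln, diagnosis, region_map)
    enc = aln.encoded()
    sl = slice(window.start_column - 1, window.end_column)
    if diagnosis.canonical and diagnosis.canonical in aln:
        # compare column-wise against the canonical's gapped window, the
        # same comparison the search used
        canon = enc[aln.row(diagnosis.canonical), sl]
    else:
        canon = iupac.encode(iupac.normalize(diagnosis.barcode))
    targets = set(aln.members_of(diagnosis.target, rank))
    fail_t, fail_n = [], []
    for m in aln.members:
        row = enc[aln.row(m.accession), sl]
        if len(row) != len(canon):
            # gapped window wider than the degapped barcode: compare the
            # member's degapped residues, surplus length counts as diffs
            row = row[row != 0]
            n = min(len(row), len(canon))
            k = int(_diff_row(canon[:n], row[:n]).sum()) + abs(len(row) - len(canon))
        else:
            k = int(_diff_row(canon, row).sum())
        if m.accession in targets:
            if k > diagnosis.reported_allowance:
                fail_t.append((m.accession, k))
        elif k <= diagnosis.reported_allowance:
            fail_n.append((m.accession, k))
    return ValidationReport(
        diagnosis=diagnosis,
        target_within_allowance=not fail_t,
        nontarget_beyond_allowance=not fail_n,
        length_consistent=diagnosis.length_consistent,
        failing_targets=fail_t,
        failing_nontargets=fail_n,
    )


def _anchor_window(aln: Alignment, diagnosis: Diagnosis,
                   region_map: RegionMap) -> WindowSpec:
    """Recover alignment columns from region-relative printed positions."""
    canon = diagnosis.canonical or aln.members_of(diagnosis.target)[0]
    index = CoordinateIndex(aln, region_map)
    c0 = index.region_position_to_column(canon, diagnosis.region,
                                         diagnosis.positions[0])
    c1 = index.region_position_to_column(canon, diagnosis.region,
                                         diagnosis.positions[1])
    return WindowSpec(c0, c1 - c0 + 1)


# ---------------------------------------------------------------------------
# Printed-diagnosis text format

_ALLOWANCE_WORDS = {0: "no", 1: "one"}


def _allowance_phrase(k: int) -> str:
    word = _ALLOWANCE_WORDS.get(k, str(k))
    noun = "mismatch" if k <= 1 else "mismatches"
    return f"{word} {noun} allowed"


def format_fragment(region_prefix: str, start: int, end: int, barcode: str,
                    allowance: int, separator: str = ";") -> str:
    """One parenthetical diagnosis fragment in the printed style.

    e.g. ``ITS2 positions 127–146 gaaccgcaaattacgcatta, one mismatch
    allowed``. *region_prefix* may be empty (bare "positions ..."); the
    separator before the allowance phrase is ";" or ",".
    """
    prefix = f"{region_prefix} " if region_prefix else ""
    return (f"{prefix}positions {start}{EN_DASH}{end} {barcode}"
            f"{separator} {_allowance_phrase(allowance)}")


_FRAGMENT_RE = re.compile(
    rf"^(?:(?P<prefix>[A-Za-z0-9.]+) )?positions (?P<start>\d+){EN_DASH}"
    r"(?P<end>\d+) (?P<barcode>[a-z]+)(?P<sep>[;,]) "
    r"(?P<word>\S+) mismatch(?:es)? allowed$"
)


def parse_fragment(text: str) -> dict:
    """Inverse of :func:`format_fragment`; raises ValueError on mismatch."""
    m = _FRAGMENT_RE.match(text)
    if m is None:
        raise ValueError(f"unparseable diagnosis fragment: {text!r}")
    word = m.group("word")
    allowance = {"no": 0, "one": 1}.get(word)
    if allowance is None:
        allowance = int(word)
    return {
        "region_prefix": m.group("prefix") or "",
        "start": int(m.group("start")),
        "end": int(m.group("end")),
        "barcode": m.group("barcode"),
        "allowance": allowance,
        "separator": m.group("sep"),
    }


def fragment_for(diagnosis: Diagnosis, bare_positions: bool = False,
                 separator: str = ";") -> str:
    prefix = "" if bare_positions else diagnosis.region
    return format_fragment(prefix, diagnosis.positions[0],
                           diagnosis.positions[1], diagnosis.barcode,
                           diagnosis.reported_allowance, separator)


def format_diagnosis(genus: str, its: Diagnosis | None,
                     lsu: Diagnosis | None,
                     its_scope: str | None = None,
                     lsu_scope: str | None = None) -> str:
    """Full diagnosis sentence in the printed style.

    Scope phrases default to "other species of <genus>"; an explicit
    *lsu_scope* (e.g. "other species of Endogonomycetes") switches the LSU
    clause to the long form used when the LSU comparison set is wider.
    """
    if its is None and lsu is None:
        raise ValueError("at least one diagnosis is required")
    scope = its_scope or f"other species of *{genus}*"
    parts = [f"Separation from {scope} based on"]
    if its is not None:
        frag = fragment_for(its, bare_positions=its.region not in ("ITS2", "5.8S"))
        parts.append(f"the ITS region ({frag})")
    if lsu is not None:
        frag = fragment_for(lsu, bare_positions=True)
        if lsu_scope:
            joiner = f"and from {lsu_scope} based on LSU" if its is not None \
                else f"{lsu_scope} based on LSU"
            parts.append(f"{joiner} ({frag})")
        elif its is not None:
            parts.append(f"and LSU ({frag})")
        else:
            parts.append(f"LSU ({frag})")
    return " ".join(parts) + "."


# ---------------------------------------------------------------------------
# Packaged transcription of the printed diagnoses

def load_printed_diagnoses() -> pd.DataFrame:
    """The 15 published species diagnoses (29 barcode fragments) as a table.

    Columns: species, genus, marker (ITS/LSU), region_prefix (ITS2/5.8S or
    empty when the print gives bare positions), start, end, barcode,
    allowance, separator, scope, provenance.
    """
    with resources.files("taxodiag.data").joinpath("printed_diagnoses.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", keep_default_na=False,
                         dtype={"start": int, "end": int, "allowance": int})
    return df


def printed_fragment(row: pd.Series) -> str:
    """Render one fixture row back into its printed fragment."""
    return format_fragment(row["region_prefix"], row["start"], row["end"],
                           row["barcode"], row["allowance"], row["separator"])


def audit_printed_diagnoses(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flag internal inconsistencies in the printed diagnoses.

    Checks span-vs-barcode-length agreement per fragment and duplicate
    barcode strings across species (a likely transcription error when two
    genera print the same 30-mer).
    """
    if df is None:
        df = load_printed_diagnoses()
    df = df.copy()
    df["span"] = df["end"] - df["start"] + 1
    df["barcode_length"] = df["barcode"].str.len()
    df["length_consistent"] = df["span"] == df["barcode_length"]
    dup = df.duplicated("barcode", keep=False)
    df["duplicate_barcode"] = dup
    return df
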