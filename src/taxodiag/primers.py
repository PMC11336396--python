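"""IUPAC-aware in-silico primer evaluation.

Primers are placed at the best (fewest-mismatch) position along each
degapped sequence; mismatches are indexed from the primer's 3' end and
classified terminal / near-terminal / central, because mismatches close
to the 3' terminus are the ones that compromise extension. Per-lineage
summaries approximate the visual evaluation of primer bias over grouped
alignments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import iupac
from .alignment import Alignment


@dataclass(frozen=True)
class Primer:
    name: str
    iupac_sequence: str            # 5'->3'
    orientation: str               # forward | reverse
    target_region: str = ""

    def __post_init__(self) -> None:
        seq = iupac.normalize(self.iupac_sequence)
        object.__setattr__(self, "iupac_sequence", seq)
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"{self.name}: bad orientation {self.orientation!r}")
        if len(seq) < 10:
            raise ValueError(f"{self.name}: primers must be >= 10 bases")
        bad = iupac.first_illegal(seq)
        if bad is not None or "-" in seq:
            raise ValueError(f"{self.name}: illegal primer character")

    def __len__(self) -> int:
        return len(self.iupac_sequence)


@dataclass
class PrimerHit:
    accession: str
    primer: str
    offset: int                     # 1-based on the degapped (strand-resolved) sequence
    mismatch_count: int
    mismatch_positions_from_3prime: list[int]
    class_counts: dict[str, int]
    found: bool = True


def iupac_compatible(primer_code: str, target_base: str,
                     target_n_matches: bool = False) -> bool:
    """True when the primer's degeneracy covers the target base.

    The target base's set must be a subset of the primer code's set; a
    fully ambiguous target ``N`` only matches a primer ``N`` unless
    *target_n_matches* treats unknown template bases as compatible.
    """
    p, t = iupac.MASK[primer_code.upper()], iupac.MASK[target_base.upper()]
    if target_n_matches and target_base.upper() == "N":
        return True
    return t != 0 and (t & ~p) == 0


def classify_position(pos_from_3prime: int, near_window: int = 3) -> str:
    """Terminal (3' base), near-terminal (within *near_window*), or central."""
    if pos_from_3prime < 1:
        raise ValueError("positions are 1-based from the 3' end")
    if pos_from_3prime == 1:
        return "terminal"
    if pos_from_3prime <= near_window:
        return "near_terminal"
    return "central"


def best_site(primer: Primer, sequence: str, accession: str = "",
              near_window: int = 3,
              target_n_matches: bool = False) -> PrimerHit:
    """Best placement of a primer along a degapped sequence.

    Reverse primers are matched against the reverse complement, so the
    reported offset is on the matched strand. Ties go to the smallest
    offset. A sequence shorter than the primer yields a flagged no-site
    hit.
    """
    seq = iupac.normalize(sequence).replace("-", "")
    if primer.orientation == "reverse":
        seq = iupac.reverse_complement(seq)
    L = len(primer)
    if len(seq) < L:
        return PrimerHit(accession, primer.name, 0, L, [], {}, found=False)
    p = iupac.encode(primer.iupac_sequence)
    s = iupac.encode(seq)
    if target_n_matches:
        # unknown template bases are treated as compatible with anything
        s = s.copy()
        s[s == 15] = 0  # sentinel: handled below
    n_sites = len(seq) - L + 1
    windows = np.lib.stride_tricks.sliding_window_view(s, L)
    if target_n_matches:
        mism = (windows & ~p[None, :]) != 0
        mism &= windows != 0
    else:
        mism = ((windows & ~p[None, :]) != 0) | (windows == 0)
    counts = mism.sum(axis=1)
    best = int(counts.argmin())       # argmin takes the first = smallest offset
    positions = [L - int(i) for i in np.flatnonzero(mism[best])]
    positions.sort()
    classes = {"terminal": 0, "near_terminal": 0, "central": 0}
    for pos in positions:
        classes[classify_position(pos, near_window)] += 1
    return PrimerHit(accession, primer.name, best + 1, int(counts[best]),
                     positions, classes)


def screen_alignment(aln: Alignment, primers: Sequence[Primer],
                     near_window: int = 3) -> list[PrimerHit]:
    """Best site of every primer against every member's degapped sequence."""
    hits = []
    for primer in primers:
        for m in aln.members:
            hits.append(best_site(primer, m.residues, m.accession,
                                  near_window=near_window))
    return hits


@dataclass
class SummaryThresholds:
    well_fraction: float = 0.9      # fraction of the group that must be clean
    max_clean_mismatches: int = 1   # a hit is clean with <= this many, central-only


def group_summary(hits: Iterable[PrimerHit],
                  grouping: Mapping[str, str],
                  thresholds: SummaryThresholds | None = None) -> pd.DataFrame:
    """Per-group primer-bias summary.

    A hit is "clean" when it has at most one mismatch and none outside
    the central zone; a primer "matches well" to a group when >= 90% of
    its sequences are clean. Groups with no mapped sequences are omitted.
    """
    th = thresholds or SummaryThresholds()
    rows: dict[tuple[str, str], list[PrimerHit]] = {}
    for hit in hits:
        if not hit.found:
            continue
        group = grouping.get(hit.accession)
        if group is None:
            continue
        rows.setdefault((hit.primer, group), []).append(hit)
    out = []
    for (primer, group), hh in sorted(rows.items()):
        n = len(hh)
        counts = np.array([h.mismatch_count for h in hh])
        clean = [h for h in hh
                 if h.mismatch_count <= th.max_clean_mismatches
                 and h.class_counts.get("terminal", 0) == 0
                 and h.class_counts.get("near_terminal", 0) == 0]
        frac_clean = len(clean) / n
        out.append({
            "primer": primer,
            "group": group,
            "n": n,
            "fraction_zero_mismatch": float((counts == 0).mean()),
            "fraction_with_terminal": float(np.mean(
                [h.class_counts.get("terminal", 0) > 0 for h in hh])),
            "fraction_with_near_terminal": float(np.mean(
                [h.class_counts.get("near_terminal", 0) > 0 for h in hh])),
            "median_mismatches": float(np.median(counts)),
            "verdict": "matches well" if frac_clean >= th.well_fraction
            else "potential bias",
        })
    return pd.DataFrame(out, columns=[
        "primer", "group", "n", "fraction_zero_mismatch",
        "fraction_with_terminal", "fraction_with_near_terminal",
        "median_mismatches", "verdict"])


def hits_json(hits: Sequence[PrimerHit]) -> str:
    return json.dumps([{
        "accession": h.accession, "primer": h.primer, "offset": h.offset,
        "mismatch_count": h.mismatch_count,
        "mismatch_positions_from_3prime": h.mismatch_positions_from_3prime,
        "class_counts": h.class_counts, "found": h.found,
    } for h in hits], indent=2)


def load_primer_table(source: str | Path | None = None
                      ) -> tuple[list[Primer], pd.DataFrame]:
    """Packaged (or user) primer table.

    Returns the primers with printed sequences plus the full table, which
    also lists named placeholders whose sequences must be supplied from
    the primer literature.
    """
    if source is None:
        with resources.files("taxodiag.data").joinpath("primers.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", keep_default_na=False)
    else:
        df = pd.read_csv(source, sep="\t", keep_default_na=False)
    primers = [Primer(r["name"], r["sequence"], r["orientation"],
                      r.get("target_region", ""))
               for _, r in df.iterrows() if r["sequence"]]
    return primers, df
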