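"""Homolog curation filters for hit tables and alignments.

Covers the numeric quality filters applied to homology-search output
(identity / coverage / E-value / length window / partial flag), per-genus
subsampling, catalytic-site conservation screening, autapomorphic
insertion detection, and alignment column trimming.  Search tools
themselves (BLAST, hmmsearch, aligners) are out of scope: this module
consumes their tabular/FASTA output.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.stats import gaussian_kde

__all__ = [
    "HitRecord",
    "FilterProfile",
    "PROFILES",
    "AlignmentMatrix",
    "filter_hits",
    "read_hits",
    "write_hits",
    "subsample_per_genus",
    "check_catalytic_sites",
    "detect_autapomorphic_insertions",
    "trim_columns",
    "length_summary",
    "REJECTION_ORDER",
]

REJECTION_ORDER = ("identity", "coverage", "evalue", "length", "partial")


@dataclass(frozen=True)
class HitRecord:
    """One homology-search hit row (BLAST outfmt-6 style, extended)."""

    query_id: str
    subject_id: str
    organism: str
    identity: float  # percent, 0-100
    coverage: float  # percent query coverage, 0-100
    evalue: float
    length: int  # subject length, residues
    partial: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 100):
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if not (0 <= self.coverage <= 100):
            raise ValueError(f"coverage {self.coverage} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")


@dataclass(frozen=True)
class FilterProfile:
    """Thresholds retained hits must meet.

    Identity and coverage are inclusive minima, the E-value cutoff is
    strict (< max), and the length window is inclusive on both ends.
    """

    name: str
    min_identity: float = 0.0
    min_coverage: float = 0.0
    max_evalue: float = math.inf
    length_window: Tuple[int, int] = (1, 10**9)

    def __post_init__(self) -> None:
        lo, hi = self.length_window
        if not lo < hi:
            raise ValueError("length window requires lo < hi")
        for v in (self.min_identity, self.min_coverage):
            if not (0 <= v <= 100):
                raise ValueError("identity/coverage thresholds must be in [0, 100]")


#: Named curation presets for the enzyme families handled by the pipeline.
PROFILES: Dict[str, FilterProfile] = {
    "nitrilase-blast": FilterProfile(
        "nitrilase-blast", min_identity=70.0, min_coverage=95.0,
        max_evalue=1e-10, length_window=(200, 500),
    ),
    "nitrilase-hmm": FilterProfile(
        "nitrilase-hmm", max_evalue=1e-10, length_window=(50, 500),
    ),
    "nhase": FilterProfile(
        "nhase", min_identity=50.0, min_coverage=75.0,
        max_evalue=1e-10, length_window=(200, 300),
    ),
    "scnase": FilterProfile(
        "scnase", min_identity=50.0, min_coverage=75.0,
        max_evalue=1e-10, length_window=(175, 300),
    ),
}


def filter_hits(
    hits: Sequence[HitRecord], profile: FilterProfile
) -> Tuple[List[HitRecord], Dict[str, int]]:
    """Apply a filter profile; rejection counts are per first-failing rule
    in the fixed order identity, coverage, evalue, length, partial."""
    retained: List[HitRecord] = []
    rejected = {rule: 0 for rule in REJECTION_ORDER}
    lo, hi = profile.length_window
    for hit in hits:
        if hit.identity < profile.min_identity:
            rejected["identity"] += 1
        elif hit.coverage < profile.min_coverage:
            rejected["coverage"] += 1
        elif not hit.evalue < profile.max_evalue:
            rejected["evalue"] += 1
        elif not lo <= hit.length <= hi:
            rejected["length"] += 1
        elif hit.partial:
            rejected["partial"] += 1
        else:
            retained.append(hit)
    return retained, rejected


_HIT_COLUMNS = (
    "query_id", "subject_id", "organism", "identity", "coverage",
    "evalue", "length", "partial",
)


def read_hits(path, column_map: Optional[Dict[str, str]] = None) -> List[HitRecord]:
    """Read a tab-separated hit table.

    The file must carry a header; ``column_map`` renames file columns to
    the canonical names (query_id, subject_id, organism, identity,
    coverage, evalue, length, partial).  Malformed rows raise with their
    line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _HIT_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    hits = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            hits.append(
                HitRecord(
                    query_id=row["query_id"],
                    subject_id=row["subject_id"],
                    organism=row["organism"],
                    identity=float(row["identity"]),
                    coverage=float(row["coverage"]),
                    evalue=float(row["evalue"]),
                    length=int(row["length"]),
                    partial=str(row.get("partial", "false")).strip().lower()
                    in ("1", "true", "yes"),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed hit row at line {line}: {exc}") from exc
    return hits


def write_hits(hits: Sequence[HitRecord], path) -> None:
    pd.DataFrame([h.__dict__ for h in hits]).to_csv(path, sep="\t", index=False)


def subsample_per_genus(items: Sequence) -> List:
    """Keep one representative per genus (first whitespace token of the
    organism string): the longest sequence, ties by lexicographic id.

    Accepts any objects with ``organism``, ``length`` and an id attribute
    (``subject_id`` or ``id``); the retained set is independent of input
    order.
    """

    def item_id(it) -> str:
        return getattr(it, "subject_id", None) or getattr(it, "id")

    best: Dict[str, object] = OrderedDict()
    for it in items:
        organism = it.organism.strip()
        if not organism:
            raise ValueError(f"empty organism string for {item_id(it)!r}")
        genus = organism.split()[0]
        cur = best.get(genus)
        if cur is None:
            best[genus] = it
            continue
        key_new = (it.length, _revstr(item_id(it)))
        key_cur = (cur.length, _revstr(item_id(cur)))
        if key_new > key_cur:
            best[genus] = it
    return [best[g] for g in sorted(best)]


class _revstr(str):
    """str with reversed ordering (so max() picks the lexicographically
    smallest id on ties)."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


# ------------------------------------------------------------- alignments


GAP_CHARS = frozenset("-.")


class AlignmentMatrix:
    """Aligned amino-acid matrix with 1-based column coordinates."""

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        if len(ids) != len(rows):
            raise ValueError("ids and rows differ in number")
        if len(set(ids)) != len(ids):
            raise ValueError("sequence ids must be unique")
        widths = {len(r) for r in rows}
        if len(widths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(widths)}")
        self.ids = list(ids)
        self.matrix = np.array([list(r.upper()) for r in rows], dtype="U1")

    @property
    def n_seqs(self) -> int:
        return self.matrix.shape[0]

    @property
    def width(self) -> int:
        return self.matrix.shape[1] if self.n_seqs else 0

    def row(self, seq_id: str) -> str:
        return "".join(self.matrix[self.ids.index(seq_id)])

    def gap_mask(self) -> np.ndarray:
        return np.isin(self.matrix, list(GAP_CHARS))

    @classmethod
    def from_fasta(cls, path) -> "AlignmentMatrix":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, sid in enumerate(self.ids):
                fh.write(f">{sid}\n{''.join(self.matrix[i])}\n")


def check_catalytic_sites(
    aln: AlignmentMatrix,
    sites: Sequence[int],
    expected: Optional[Sequence[str]] = None,
    adjacency: int = 1,
    require_residue: bool = False,
) -> Tuple[List[str], pd.DataFrame]:
    """Flag sequences with gaps at or adjacent to conserved catalytic
    columns (1-based), optionally also requiring the expected residue.

    Returns (violator ids, per-site report).
    """
    for s in sites:
        if not 1 <= s <= aln.width:
            raise ValueError(f"site column {s} outside alignment width {aln.width}")
    if expected is not None and len(expected) != len(sites):
        raise ValueError("expected residues must match the number of sites")
    gaps = aln.gap_mask()
    violators: Set[str] = set()
    report_rows = []
    for si, s in enumerate(sites):
        lo = max(s - adjacency, 1) - 1
        hi = min(s + adjacency, aln.width)  # exclusive
        window_gap = gaps[:, lo:hi].any(axis=1)
        mismatch = np.zeros(aln.n_seqs, dtype=bool)
        if require_residue and expected is not None:
            mismatch = (aln.matrix[:, s - 1] != expected[si].upper()) & ~gaps[:, s - 1]
        bad = window_gap | mismatch
        for i in np.flatnonzero(bad):
            violators.add(aln.ids[i])
        report_rows.append(
            {
                "site": s,
                "n_gap_violations": int(window_gap.sum()),
                "n_residue_mismatches": int(mismatch.sum()),
            }
        )
    return sorted(violators), pd.DataFrame(report_rows)


def detect_autapomorphic_insertions(
    aln: AlignmentMatrix, min_run: int = 20, gap_majority: float = 0.95
) -> List[str]:
    """Flag sequences holding a residue run of >= ``min_run`` columns where
    at least ``gap_majority`` of the *other* sequences are gapped."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    gaps = aln.gap_mask()
    n = aln.n_seqs
    if n < 2:
        return []
    gap_counts = gaps.sum(axis=0)  # per column, all sequences
    flagged = []
    for i in range(n):
        # fraction of OTHER sequences gapped in each column
        others_gapped = gap_counts - gaps[i].astype(int)
        frac = others_gapped / (n - 1)
        private = (~gaps[i]) & (frac >= gap_majority)
        run = 0
        hit = False
        for col in private:
            run = run + 1 if col else 0
            if run >= min_run:
                hit = True
                break
        if hit:
            flagged.append(aln.ids[i])
    return flagged


def trim_columns(aln: AlignmentMatrix, first_keep: int, last_keep: int) -> AlignmentMatrix:
    """Keep the inclusive 1-based column range [first_keep, last_keep]."""
    if not 1 <= first_keep <= last_keep <= aln.width:
        raise ValueError(
            f"invalid trim range [{first_keep}, {last_keep}] for width {aln.width}"
        )
    sub = aln.matrix[:, first_keep - 1 : last_keep]
    return AlignmentMatrix(aln.ids, ["".join(r) for r in sub])


def length_summary(
    lengths: Sequence[float], rel_height: float = 0.10, grid_points: int = 512
):
    """Gaussian-KDE length profile plus an advisory retention window.

    The window is the contiguous interval around the main mode where the
    density stays above ``rel_height`` of the peak.  Filtering always uses
    an explicit :class:`FilterProfile`; this is a plotting/advisory aid.
    Returns (grid, density, (window_lo, window_hi)).
    """
    x = np.asarray(lengths, dtype=float)
    if len(x) < 5:
        raise ValueError("need >= 5 lengths")
    if np.ptp(x) == 0:
        v = float(x[0])
        return np.array([v]), np.array([np.inf]), (v, v)
    kde = gaussian_kde(x, bw_method="silverman")
    pad = 3.0 * x.std(ddof=1)
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_points)
    dens = kde(grid)
    peak = int(np.argmax(dens))
    cut = rel_height * dens[peak]
    lo = peak
    while lo > 0 and dens[lo - 1] >= cut:
        lo -= 1
    hi = peak
    while hi < len(grid) - 1 and dens[hi + 1] >= cut:
        hi += 1
    return grid, dens, (float(grid[lo]), float(grid[hi]))
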