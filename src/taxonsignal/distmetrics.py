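"""Uncorrected p-distances and their within-group / overall summaries.

p-distance = mismatches / compared sites, comparing only positions where
both sequences carry an unambiguous base (pairwise deletion). IUPAC
ambiguity codes other than A/C/G/T are excluded from the comparison, not
partially matched; this mirrors common barcode practice and the defaults
of the distance software the summaries emulate.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .congruence import ConcordanceGroup
from .treekit import Alignment

__all__ = ["p_distance", "summarize_distances", "DistanceSummary"]

_UNAMBIGUOUS = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.zeros(arr.size, dtype=np.uint8)
    valid = np.zeros(arr.size, dtype=bool)
    for base, code in _UNAMBIGUOUS.items():
        hit = arr == ord(base)
        codes[hit] = code
        valid |= hit
    return codes, valid


def p_distance(a: str, b: str) -> float:
    """Uncorrected p-distance between two aligned sequences.

    Returns NaN (no comparable sites) rather than a number when every
    position is ambiguous in at least one of the two sequences.
    """
    if len(a) != len(b):
        raise ValueError(
            f"sequence length mismatch: {len(a)} vs {len(b)}")
    ca, va = _encode(a)
    cb, vb = _encode(b)
    both = va & vb
    n = int(both.sum())
    if n == 0:
        return float("nan")
    mism = int(((ca != cb) & both).sum())
    return mism / n


@dataclass
class DistanceSummary:
    """Mean pairwise p-distances within each group and overall.

    Cells that cannot be computed (groups with fewer than two members,
    or no comparable sites) are NaN and listed in ``flags``; they are
    never zero-filled. ``n_pairs`` counts the unordered pairs behind
    each mean.
    """

    per_group_mean: dict
    overall_mean: float
    n_pairs: dict
    flags: list = field(default_factory=list)

    def within_group_grand_mean(self) -> float:
        vals = [v for v in self.per_group_mean.values() if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["group", "mean_p_distance", "n_pairs"])
            for name in sorted(self.per_group_mean):
                writer.writerow([name, self.per_group_mean[name],
                                 self.n_pairs[name]])
            writer.writerow(["__overall__", self.overall_mean,
                             self.n_pairs["__overall__"]])


def _pair_sums(codes: np.ndarray, valid: np.ndarray) -> tuple[float, int, int]:
    """Sum of pairwise p-distances and pair count over the rows given."""
    n = codes.shape[0]
    total = 0.0
    pairs = 0
    skipped = 0
    for i in range(n - 1):
        both = valid[i + 1:] & valid[i]
        comp = both.sum(axis=1)
        mism = ((codes[i + 1:] != codes[i]) & both).sum(axis=1)
        ok = comp > 0
        total += float((mism[ok] / comp[ok]).sum())
        pairs += int(ok.sum())
        skipped += int((~ok).sum())
    return total, pairs, skipped


def summarize_distances(alignment: Alignment,
                        groups: Sequence[ConcordanceGroup]) -> DistanceSummary:
    """Unweighted means over unordered pairs, per group and matrix-wide."""
    codes = np.empty((alignment.n_taxa, alignment.length), dtype=np.uint8)
    valid = np.empty_like(codes, dtype=bool)
    for i, seq in enumerate(alignment.seqs):
        codes[i], valid[i] = _encode(seq)
    row = {t: i for i, t in enumerate(alignment.ids)}

    per_group: dict = {}
    n_pairs: dict = {}
    flags: list[str] = []
    for g in sorted(groups, key=lambda g: g.name):
        idx = [row[t] for t in sorted(g.members) if t in row]
        if len(idx) < 2:
            per_group[g.name] = float("nan")
            n_pairs[g.name] = 0
            flags.append(f"group_{g.name}_fewer_than_two_members")
            continue
        total, pairs, skipped = _pair_sums(codes[idx], valid[idx])
        if skipped:
            flags.append(f"group_{g.name}_{skipped}_incomparable_pairs")
        per_group[g.name] = total / pairs if pairs else float("nan")
        n_pairs[g.name] = pairs

    total, pairs, skipped = _pair_sums(codes, valid)
    if skipped:
        flags.append(f"overall_{skipped}_incomparable_pairs")
    overall = total / pairs if pairs else float("nan")
    n_pairs["__overall__"] = pairs
    return DistanceSummary(per_group_mean=per_group, overall_mean=overall,
                           n_pairs=n_pairs, flags=flags)
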