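"""Taxonomic-congruence scoring: TCI and TRI.

Phylogenetic signal is assessed by coding membership of each concordance
group (here, a family) as a binary character and counting its parsimony
steps on the estimated cladogram. For group *t* with ``n_t`` members on a
tree of *N* leaves:

* ``m_t = 1`` — minimum steps, a single origin (monophyly);
* ``s_t`` — observed Fitch steps of the membership character, i.e. the
  number of clades the group falls into on the (unrooted) tree;
* ``g_t = min(n_t, N - n_t)`` — steps on the completely unresolved tree.

The ensemble taxon consistency index is ``TCI = M/S`` and the taxon
retention index ``TRI = (G - S)/(G - M)``, with ``M = sum m_t`` etc.
Both equal 1 exactly when every group is monophyletic; TRI is 0 at
maximal scatter. Aggregation is ratio-of-sums (ensemble), not a mean of
per-group ratios. Groups with ``g_t = m_t`` (singletons, or groups
spanning all but one leaf) carry no retention information: they are
excluded from the TRI sums, flagged, but kept in M and S for the TCI.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .treekit import (
    CharacterColumn,
    EncodedMatrix,
    Tree,
    TreeError,
    tree_pattern_lengths,
)

__all__ = [
    "ConcordanceGroup",
    "CongruenceResult",
    "code_membership",
    "score_congruence",
    "clades_per_group",
    "read_groups_csv",
    "write_groups_csv",
    "round_score",
]


@dataclass(frozen=True)
class ConcordanceGroup:
    """A named taxon set (a family) used as a unit of congruence."""

    name: str
    members: frozenset

    def __post_init__(self):
        if not self.name:
            raise ValueError("group name must be non-empty")
        if not self.members:
            raise ValueError(f"group {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))

    @property
    def size(self) -> int:
        return len(self.members)


def _validate_groups(groups: Sequence[ConcordanceGroup]) -> None:
    seen: dict[str, str] = {}
    for g in groups:
        for t in g.members:
            if t in seen:
                raise ValueError(
                    f"taxon {t!r} in both group {seen[t]!r} and {g.name!r}; "
                    "concordance groups must be disjoint")
            seen[t] = g.name


def code_membership(taxa: Sequence[str],
                    groups: Sequence[ConcordanceGroup],
                    ) -> dict[str, CharacterColumn]:
    """One binary membership character per group (1 = member).

    Raises ``KeyError`` naming the taxon and group if a member is absent
    from ``taxa``.
    """
    _validate_groups(groups)
    taxa = list(taxa)
    taxon_set = set(taxa)
    columns: dict[str, CharacterColumn] = {}
    for g in groups:
        missing = g.members - taxon_set
        if missing:
            raise KeyError(
                f"member {sorted(missing)[0]!r} of group {g.name!r} "
                "absent from the taxon list")
        columns[g.name] = CharacterColumn.from_membership(taxa, g.members)
    return columns


def round_score(x: float, ndigits: int = 2) -> float:
    """Half-to-even rounding used for reported congruence scores."""
    return float(np.round(x, ndigits))


@dataclass
class CongruenceResult:
    """Per-group step counts and the ensemble TCI/TRI.

    ``per_group`` has one row per group: name, n (members), m, s, g,
    retention_informative, share_tri (fraction of retained synapomorphy
    (G-S) attributable to the group) and share_tci (m_t/M weighting).
    ``tri`` is NaN when no group is retention-informative (flagged).
    """

    per_group: pd.DataFrame
    M: int
    S: int
    G: int
    tci: float
    tri: float
    flags: list = field(default_factory=list)

    @property
    def per_group_share(self) -> dict:
        return dict(zip(self.per_group["group"], self.per_group["share_tri"]))

    def to_frame(self) -> pd.DataFrame:
        """Group rows plus an ensemble row, as written to CSV."""
        rows = self.per_group.copy()
        ensemble = pd.DataFrame([{
            "group": "__ensemble__",
            "n": int(rows["n"].sum()), "m": self.M, "s": self.S, "g": self.G,
            "retention_informative": bool(rows["retention_informative"].any()),
            "share_tri": float("nan"), "share_tci": float("nan"),
            "tci": self.tci, "tri": self.tri,
        }])
        rows["tci"] = float("nan")
        rows["tri"] = float("nan")
        return pd.concat([rows, ensemble], ignore_index=True)


def score_congruence(tree: Tree,
                     groups: Sequence[ConcordanceGroup]) -> CongruenceResult:
    """Score the taxonomic congruence of ``tree`` with ``groups``.

    Members of every group must be leaves of the tree; leaves belonging
    to no group are allowed (they only enter through N in ``g_t``).
    ``s_t`` is the Fitch length of the membership character, which on an
    unrooted tree equals the number of contiguous clusters the group
    forms (the paper-style "clades per family").
    """
    _validate_groups(groups)
    leaves = tree.leaf_labels()
    n_leaves = len(leaves)
    columns = code_membership(leaves, groups)
    names = [g.name for g in groups]
    enc = EncodedMatrix.from_columns([columns[n] for n in names], taxa=leaves)
    s_by_pattern = tree_pattern_lengths(tree, enc)
    s = s_by_pattern[enc.col_to_pattern]

    records = []
    flags: list[str] = []
    for g, s_t in zip(groups, s):
        n_t = g.size
        g_t = min(n_t, n_leaves - n_t)
        m_t = 1 if 0 < n_t < n_leaves else 0
        s_t = int(s_t)
        informative = g_t > m_t
        if not informative:
            flags.append(f"group_{g.name}_not_retention_informative")
        records.append({"group": g.name, "n": n_t, "m": m_t, "s": s_t,
                        "g": g_t, "retention_informative": informative})
    frame = pd.DataFrame.from_records(records)
    M = int(frame["m"].sum())
    S = int(frame["s"].sum())
    G = int(frame["g"].sum())
    if S == 0:
        raise TreeError("no scoreable group (all groups constant)")
    tci = M / S
    inf = frame["retention_informative"]
    Gp = int(frame.loc[inf, "g"].sum())
    Sp = int(frame.loc[inf, "s"].sum())
    Mp = int(frame.loc[inf, "m"].sum())
    if not inf.any():
        flags.append("all_groups_uninformative_tri_undefined")
        tri = float("nan")
    else:
        tri = (Gp - Sp) / (Gp - Mp)
    # contribution shares: retained synapomorphy for TRI, m-weight for TCI
    if inf.any() and Gp > Sp:
        frame["share_tri"] = np.where(
            inf, (frame["g"] - frame["s"]) / (Gp - Sp), 0.0)
    else:
        frame["share_tri"] = float("nan")
    frame["share_tci"] = frame["m"] / M if M else float("nan")
    return CongruenceResult(per_group=frame, M=M, S=S, G=G,
                            tci=tci, tri=tri, flags=flags)


def clades_per_group(result: CongruenceResult) -> tuple[dict, float]:
    """Per-group clade counts ``s_t`` and their mean (= S / group count)."""
    counts = dict(zip(result.per_group["group"], result.per_group["s"]))
    return counts, result.S / len(result.per_group)


# ---------------------------------------------------------------------------
# Group-table CSV I/O (columns: taxon_id, group_name)
# ---------------------------------------------------------------------------

def read_groups_csv(path) -> list[ConcordanceGroup]:
    by_name: dict[str, set] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                {"taxon_id", "group_name"} - set(reader.fieldnames):
            raise ValueError(
                f"{path}: expected columns taxon_id, group_name")
        for row in reader:
            by_name.setdefault(row["group_name"], set()).add(row["taxon_id"])
    groups = [ConcordanceGroup(name, frozenset(members))
              for name, members in sorted(by_name.items())]
    _validate_groups(groups)
    return groups


def write_groups_csv(groups: Sequence[ConcordanceGroup], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["taxon_id", "group_name"])
        for g in sorted(groups, key=lambda g: g.name):
            for t in sorted(g.members):
                writer.writerow([t, g.name])
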