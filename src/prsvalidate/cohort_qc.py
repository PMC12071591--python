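"""Cohort exclusion rules and ancestry grouping.

Implements the pre-analysis filters: first-degree relatedness pruning
(one member of an isolated pair removed at random; every member of a
cluster with two or more first-degree links removed), exclusion of
carriers of pathogenic/likely-pathogenic variants in high-penetrance
breast-cancer genes, and assignment of samples to continental-ancestry
majority groups.  All removals are tracked in an arithmetic-checked
:class:`ExclusionLedger`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .formats_io import KinshipPair, SampleRecord

#: genes whose P/LP carriers confer OR > 5 and are excluded before analysis
HIGH_PENETRANCE_GENES = frozenset({"BRCA1", "BRCA2", "TP53", "PALB2", "PTEN"})

#: KING-style kinship-coefficient band for first-degree relationships
FIRST_DEGREE_COEFF_BAND = (0.177, 0.354)

ANCESTRY_GROUP_LABELS = ("EAS-majority", "NonEUR-majority", "EUR-majority")


class LedgerError(ValueError):
    """Exclusion bookkeeping does not reconcile."""


@dataclass
class ExclusionLedger:
    """Auditable accounting of every sample removal stage.

    Invariants enforced at construction: removal id sets are pairwise
    disjoint and ``final_n = initial_n - sum(removals)``.
    """

    initial_n: int
    removed_relatedness: list[str] = field(default_factory=list)
    removed_missing_inputs: list[str] = field(default_factory=list)
    removed_low_quality: list[str] = field(default_factory=list)
    removed_carriers: list[str] = field(default_factory=list)
    final_cases: int = 0
    final_controls: int = 0

    def __post_init__(self) -> None:
        stages = [self.removed_relatedness, self.removed_missing_inputs,
                  self.removed_low_quality, self.removed_carriers]
        all_ids = [i for stage in stages for i in stage]
        if len(set(all_ids)) != len(all_ids):
            raise LedgerError("a sample id appears in more than one removal stage")
        if self.final_n < 0:
            raise LedgerError("more removals than initial samples")
        if self.final_cases + self.final_controls not in (0, self.final_n):
            raise LedgerError(
                f"final case+control counts ({self.final_cases}+{self.final_controls}) "
                f"do not total final_n ({self.final_n})"
            )

    @property
    def n_removed(self) -> int:
        return (len(self.removed_relatedness) + len(self.removed_missing_inputs)
                + len(self.removed_low_quality) + len(self.removed_carriers))

    @property
    def final_n(self) -> int:
        return self.initial_n - self.n_removed

    def to_dict(self) -> dict:
        return {
            "initial_n": self.initial_n,
            "removed_relatedness": len(self.removed_relatedness),
            "removed_missing_inputs": len(self.removed_missing_inputs),
            "removed_low_quality": len(self.removed_low_quality),
            "removed_carriers": len(self.removed_carriers),
            "final_n": self.final_n,
            "final_cases": self.final_cases,
            "final_controls": self.final_controls,
        }


@dataclass
class AncestryGroup:
    """One ancestry-majority stratum and its member sample ids."""

    label: str
    member_ids: list[str]

    def __post_init__(self) -> None:
        if self.label not in ANCESTRY_GROUP_LABELS:
            raise ValueError(f"unknown ancestry group label {self.label!r}")


def _is_first_degree(pair: KinshipPair) -> bool:
    if pair.degree is not None:
        return pair.degree == 1
    lo, hi = FIRST_DEGREE_COEFF_BAND
    return lo <= pair.coefficient <= hi


def prune_related(
    sample_ids: list[str],
    kin_pairs: list[KinshipPair],
    seed: int,
) -> tuple[list[str], list[str]]:
    """Remove samples so that no first-degree relationship remains.

    Build the graph of first-degree edges.  For a connected component in
    which any member has two or more first-degree links, every member of
    the component is removed.  For an isolated pair, one member is removed,
    chosen by a seeded RNG for reproducibility.  Returns
    ``(kept_ids, removed_ids)`` with kept order preserved.
    """
    ids = set(sample_ids)
    graph = nx.Graph()
    for p in kin_pairs:
        if _is_first_degree(p) and p.sample_a in ids and p.sample_b in ids:
            graph.add_edge(p.sample_a, p.sample_b)
    rng = np.random.default_rng(seed)
    removed: set[str] = set()
    for comp in sorted(nx.connected_components(graph), key=min):
        if len(comp) == 2 and all(graph.degree[n] == 1 for n in comp):
            victim = rng.choice(sorted(comp))
            removed.add(str(victim))
        else:
            removed.update(comp)
    kept = [s for s in sample_ids if s not in removed]
    return kept, sorted(removed)


def exclude_carriers(
    samples: list[SampleRecord],
    genes: frozenset | set = HIGH_PENETRANCE_GENES,
) -> tuple[list[SampleRecord], list[SampleRecord]]:
    """Split samples into (kept, removed) by P/LP carrier flags in ``genes``."""
    removed = [s for s in samples if any(s.carrier_flags.get(g, False) for g in genes)]
    removed_ids = {s.sample_id for s in removed}
    kept = [s for s in samples if s.sample_id not in removed_ids]
    return kept, removed


def assign_ancestry_groups(
    samples: list[SampleRecord],
) -> tuple[list[AncestryGroup], list[str]]:
    """Partition samples with ancestry proportions into majority groups.

    Rules (in precedence order): EAS-majority when q_EAS > 0.5; otherwise
    NonEUR-majority when q_EUR <= 0.5 (the 0-50% interval is right-closed);
    otherwise EUR-majority.  Samples lacking proportions are returned
    unassigned.
    """
    members: dict[str, list[str]] = {lbl: [] for lbl in ANCESTRY_GROUP_LABELS}
    unassigned: list[str] = []
    for s in samples:
        q = s.ancestry_props
        if not q:
            unassigned.append(s.sample_id)
            continue
        if q.get("EAS", 0.0) > 0.5:
            members["EAS-majority"].append(s.sample_id)
        elif q.get("EUR", 0.0) <= 0.5:
            members["NonEUR-majority"].append(s.sample_id)
        else:
            members["EUR-majority"].append(s.sample_id)
    groups = [AncestryGroup(lbl, ids) for lbl, ids in members.items()]
    return groups, unassigned


def build_ledger(
    initial_n: int,
    removed_relatedness=(),
    removed_missing_inputs=(),
    removed_low_quality=(),
    removed_carriers=(),
    final_cases: int = 0,
    final_controls: int = 0,
) -> ExclusionLedger:
    """Assemble and arithmetic-check the exclusion ledger."""
    return ExclusionLedger(
        initial_n=initial_n,
        removed_relatedness=list(removed_relatedness),
        removed_missing_inputs=list(removed_missing_inputs),
        removed_low_quality=list(removed_low_quality),
        removed_carriers=list(removed_carriers),
        final_cases=final_cases,
        final_controls=final_controls,
    )
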