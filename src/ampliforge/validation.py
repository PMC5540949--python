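"""Utilities for validating pipeline output against a known mock community.

These map inferred OTUs back to the simulator's reference sequence classes
and compare inferred with expected composition — the standard way a
mock-community benchmark is scored.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .otu_inference import OtuTable, pairwise_identity
from .simulate import AMPLICON_INSERT_LEN, FORWARD_PRIMER, GENE_LEN, REVERSE_PRIMER, ReferenceSpecies

__all__ = [
    "class_amplicon_prefixes",
    "match_otus_to_classes",
    "expected_class_abundances",
    "composition_correlation",
    "groups_monophyletic",
]


def class_amplicon_prefixes(
    references: Sequence[ReferenceSpecies], trunclen: int = 250
) -> dict[int, str]:
    """The error-free pipeline product of each sequence class: the primer-
    trimmed amplicon insert truncated to the filter length."""
    pad = (GENE_LEN - len(FORWARD_PRIMER) - AMPLICON_INSERT_LEN - len(REVERSE_PRIMER)) // 2
    out: dict[int, str] = {}
    for ref in references:
        insert = ref.gene[pad + len(FORWARD_PRIMER) : pad + len(FORWARD_PRIMER) + AMPLICON_INSERT_LEN]
        out[ref.seq_class] = insert[:trunclen]
    return out


def match_otus_to_classes(
    table: OtuTable,
    references: Sequence[ReferenceSpecies],
    trunclen: int = 250,
    cutoff: float = 0.97,
) -> dict[str, int | None]:
    """Assign each OTU centroid to the sequence class it represents (best
    identity >= cutoff), or None for an unexpected OTU."""
    prefixes = class_amplicon_prefixes(references, trunclen)
    out: dict[str, int | None] = {}
    for otu in table.otus:
        best_cls, best_ident = None, -1.0
        for cls, seq in prefixes.items():
            ident = pairwise_identity(otu.centroid, seq)
            if ident > best_ident:
                best_cls, best_ident = cls, ident
        out[otu.otu_id] = best_cls if best_ident >= cutoff else None
    return out


def expected_class_abundances(
    references: Sequence[ReferenceSpecies], species_abundances: Sequence[float]
) -> dict[int, float]:
    """Sum species-level expected abundances within each sequence class
    (indistinguishable strains pool into one class)."""
    out: dict[int, float] = {}
    for ref, a in zip(references, species_abundances):
        out[ref.seq_class] = out.get(ref.seq_class, 0.0) + float(a)
    return out


def composition_correlation(
    table: OtuTable,
    sample: str,
    otu_to_class: Mapping[str, int | None],
    expected: Mapping[int, float],
) -> float:
    """Pearson r between expected and inferred class relative abundances in
    one sample (classes absent from the table count as zero)."""
    counts = table.sample_counts(sample).astype(float)
    total = counts.sum()
    inferred: dict[int, float] = {cls: 0.0 for cls in expected}
    for j, oid in enumerate(table.otu_ids):
        cls = otu_to_class.get(oid)
        if cls is not None and cls in inferred:
            inferred[cls] += counts[j] / total
    classes = sorted(expected)
    x = np.array([expected[c] for c in classes])
    y = np.array([inferred[c] for c in classes])
    return float(np.corrcoef(x, y)[0, 1])


def groups_monophyletic(tree, groups: Mapping[str, str]) -> bool:
    """True iff every group's samples form their own clade on the tree."""
    tips = {t.name: t for t in tree.tips()}
    by_group: dict[str, list] = {}
    for name, g in groups.items():
        if name in tips:
            by_group.setdefault(g, []).append(tips[name])
    for g, members in by_group.items():
        if len(members) < 2:
            continue
        clade = tree.lca(members)
        if {t.name for t in clade.tips()} != {m.name for m in members}:
            return False
    return True
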