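"""Stage 2 of index derivation: phi-coefficient grouping and consolidation.

Pairs of retained procedures with phi > 0.6 are linked; connected components
of that graph form correlation groups.  Each group is resolved by one of two
clinically motivated policies: procedures usually performed *simultaneously*
are combined into a single any-of indicator; for procedures performed
*consecutively* only the one usually performed first is kept.  Which policy
applies is domain knowledge and therefore configuration; unconfigured groups
fall back to combine_any_of with a warning.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ConfigError, ZeroMarginError
from .screening import TwoByTwo

POLICIES = ("combine_any_of", "keep_named_first")


@dataclass(frozen=True)
class CorrelationGroup:
    members: Tuple[str, ...]
    policy: Optional[str] = None
    arg: Optional[str] = None  # combined name, or the member to keep

    def __post_init__(self):
        if len(self.members) < 2:
            raise ConfigError("a correlation group needs at least 2 members")
        if self.policy is not None:
            if self.policy not in POLICIES:
                raise ConfigError(f"unknown policy {self.policy!r}")
            if self.arg is None:
                raise ConfigError(f"policy {self.policy!r} needs an argument")
            if (self.policy == "keep_named_first"
                    and self.arg not in self.members):
                raise ConfigError(
                    f"keep_named_first argument {self.arg!r} is not a member")


def phi(t: TwoByTwo) -> float:
    """Phi coefficient of a 2x2 cross-tabulation of two binary variables:
    (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)).  Lies in [-1, 1]; undefined
    (raises :class:`ZeroMarginError`) when a margin is empty."""
    r1, r2, c1, c2 = t.margins
    if min(r1, r2, c1, c2) == 0:
        raise ZeroMarginError(f"zero margin in table {t}")
    return (t.a * t.d - t.b * t.c) / np.sqrt(
        float(r1) * r2 * c1 * c2)


def phi_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """All pairwise phi coefficients of binary feature columns."""
    X = features.to_numpy(dtype=np.float64)
    n = X.shape[0]
    n11 = X.T @ X
    ones = X.sum(axis=0)
    num = n * n11 - np.outer(ones, ones)
    var = ones * (n - ones)
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / denom
    return pd.DataFrame(out, index=features.columns, columns=features.columns)


def find_groups(features: pd.DataFrame, threshold: float = 0.6) -> list:
    """Correlation groups among binary features.

    Groups are the connected components of the graph with an edge wherever
    pairwise phi exceeds ``threshold`` (strictly); singletons are omitted and
    returned groups carry no policy yet.  Components (rather than cliques)
    make the result deterministic and order-independent.
    """
    cols = list(features.columns)
    if len(cols) < 2:
        return []
    pm = phi_matrix(features).to_numpy()
    adj = np.triu(pm > threshold, k=1)
    graph = csr_matrix(adj)
    n_comp, labels = connected_components(graph, directed=False)
    groups = []
    for comp in range(n_comp):
        members = tuple(c for c, l in zip(cols, labels) if l == comp)
        if len(members) >= 2:
            groups.append(CorrelationGroup(members))
    return groups


def consolidated_catalog(catalog, groups: Sequence[CorrelationGroup]):
    """Apply group policies at the catalog level, so consolidated variables
    can be extracted straight from raw event codes: combine_any_of entries
    match the union of their members' codes, keep_named_first keeps only the
    named member's entry."""
    from .cohort import CatalogEntry, FeatureCatalog

    by_name = {e.name: e for e in catalog.entries}
    dropped = set()
    combined = []
    for g in groups:
        for m in g.members:
            if m not in by_name:
                raise ConfigError(f"group member {m!r} not in catalog")
        if g.policy is None:
            arg = "combined_" + "_".join(sorted(g.members))
            warnings.warn(
                f"correlation group {g.members} has no configured policy; "
                f"defaulting to combine_any_of as {arg!r}", stacklevel=2)
            g = replace(g, policy="combine_any_of", arg=arg)
        if g.policy == "combine_any_of":
            codes = tuple(dict.fromkeys(
                c for m in g.members for c in by_name[m].codes))
            combined.append(CatalogEntry(g.arg, codes))
            dropped.update(g.members)
        else:  # keep_named_first
            dropped.update(m for m in g.members if m != g.arg)
    entries = [e for e in catalog.entries if e.name not in dropped]
    return FeatureCatalog(entries + combined)


def resolve(features: pd.DataFrame, groups: Sequence[CorrelationGroup]
            ) -> Tuple[pd.DataFrame, list]:
    """Consolidate the feature matrix according to the group policies.

    combine_any_of replaces the member columns by their pointwise maximum
    under the combined name; keep_named_first keeps only the named member.
    Features in no group pass through untouched (column order preserved,
    combined columns appended in group order).  Unconfigured groups default
    to combine_any_of over their members, with a warning.
    """
    out = features.copy()
    seen = set()
    for g in groups:
        for m in g.members:
            if m not in out.columns:
                raise ConfigError(f"group member {m!r} not in feature matrix")
            if m in seen:
                raise ConfigError(f"feature {m!r} appears in several groups")
            seen.add(m)
        if g.policy is None:
            arg = "combined_" + "_".join(sorted(g.members))
            warnings.warn(
                f"correlation group {g.members} has no configured policy; "
                f"defaulting to combine_any_of as {arg!r}", stacklevel=2)
            g = replace(g, policy="combine_any_of", arg=arg)
        if g.policy == "combine_any_of":
            combined = out[list(g.members)].max(axis=1)
            out = out.drop(columns=list(g.members))
            out[g.arg] = combined
        else:  # keep_named_first
            drop = [m for m in g.members if m != g.arg]
            out = out.drop(columns=drop)
    return out, list(out.columns)
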