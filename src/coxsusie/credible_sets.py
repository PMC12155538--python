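"""Credible set construction, purity filtering and sentinel reporting.

A level-rho credible set (CS) is a subset of variants that has posterior
probability >= rho of containing the effect variable of one single
effect.  Given an effect's alpha vector, the CS is the minimal greedy
prefix of variants sorted by descending alpha whose cumulative mass
reaches rho.  A CS spanning many mutually uncorrelated variants carries
no fine-mapping information, so sets whose *purity* — the smallest
absolute pairwise Pearson correlation among members — falls below a
threshold (default 0.5) are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gibss import SusieFit

__all__ = ["CredibleSet", "build_credible_set", "purity",
           "extract_credible_sets"]


@dataclass(frozen=True)
class CredibleSet:
    """One credible set from one single effect."""

    effect_index: int          # which effect l (0-based)
    members: tuple[int, ...]   # variant indices, descending alpha
    rho: float                 # target level
    attained_mass: float       # sum of member alphas (>= rho)
    purity: float              # min |r| over member pairs; 1 for singleton
    sentinel: int              # member with the largest alpha
    sentinel_pip: float        # overall PIP of the sentinel

    @property
    def label(self) -> str:
        return f"L{self.effect_index + 1}"

    @property
    def size(self) -> int:
        return len(self.members)


def build_credible_set(alpha: np.ndarray, rho: float) -> list[int]:
    """Minimal descending-alpha prefix with cumulative mass >= rho.

    Ties in alpha are broken by ascending variant index, so the output
    is deterministic.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    if abs(alpha.sum() - 1.0) > 1e-8:
        raise ValueError("alpha must sum to 1")
    order = np.lexsort((np.arange(len(alpha)), -alpha))
    cum = np.cumsum(alpha[order])
    k = int(np.searchsorted(cum, rho - 1e-12)) + 1
    return [int(j) for j in order[:min(k, len(alpha))]]


def purity(members, X: np.ndarray) -> float:
    """Smallest absolute pairwise Pearson correlation among CS members.

    A singleton set has purity 1 by convention (the filter is a no-op for
    it).  Zero-variance member columns contribute correlation 0 to every
    pair they appear in, with a warning.
    """
    members = list(members)
    if len(members) == 0:
        raise ValueError("credible set has no members")
    if len(members) == 1:
        return 1.0
    cols = np.asarray(X, dtype=np.float64)[:, members]
    sd = cols.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("zero-variance column in credible set; treating its "
                      "correlations as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(cols, rowvar=False)
    r = np.where(np.isfinite(r), r, 0.0)
    iu = np.triu_indices(len(members), k=1)
    return float(np.min(np.abs(r[iu])))


def extract_credible_sets(fit: SusieFit, X: np.ndarray, rho: float = 0.95,
                          min_purity: float = 0.5) -> list[CredibleSet]:
    """Build, purity-filter and deduplicate the credible sets of a fit.

    One candidate CS per non-null effect; sets with purity below
    ``min_purity`` are dropped; identical member sets across effects are
    reported once (lowest effect index wins).  The sentinel is the member
    with the largest within-effect alpha, ties broken by ascending index.
    """
    X = np.asarray(X, dtype=np.float64)
    out: list[CredibleSet] = []
    seen: set[frozenset] = set()
    for l, ser in enumerate(fit.sers):
        if fit.null_effect[l] or ser is None:
            continue
        members = build_credible_set(ser.alpha, rho)
        key = frozenset(members)
        if key in seen:
            continue
        pur = purity(members, X)
        if pur < min_purity:
            continue
        seen.add(key)
        out.append(CredibleSet(
            effect_index=l,
            members=tuple(members),
            rho=rho,
            attained_mass=float(ser.alpha[members].sum()),
            purity=pur,
            sentinel=members[0],
            sentinel_pip=float(fit.pip[members[0]]),
        ))
    return out
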