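"""Age-structured matrix population model composed from vital-rate draws.

Fecundity per female combines the nesting process over first and second
attempts:

    g = (np1 * c1 * ns1 * h * cs * js) + ((1 - ns1) * np2 * c2 * ns2 * h * cs * js)

where ``np`` is nest propensity, ``c`` clutch size, ``ns`` nest survival,
``h`` hatchability, ``cs`` chick survival to 50 days and ``js`` juvenile
survival — each a posterior (or informative-prior) draw, indexed by age
class where estimated.  Abundance advances by

    NT[j+1] = sum_a NT[j,a] * g[j,a] / 2  +  sum_a NT[j,a] * jan[j,a]

(the divisor 2 assumes an equal sex ratio at hatch), and the finite rate of
change is ``lambda_P = NT[j+1] / NT[j]`` on the age-summed totals.  Recruits
enter the yearling class and surviving yearlings graduate to adults; a
flag reproduces the literal total-only recursion instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VitalRates", "fecundity", "project", "impact_delta"]

_PROB_STAGES = ("np1", "ns1", "h", "cs", "js", "np2", "ns2")


@dataclass
class VitalRates:
    """Aligned per-draw stage parameters for one age class (or broadcast
    across ages when a stage is age-invariant).  Probabilities must lie in
    [0, 1]; clutch sizes are positive counts."""

    np1: np.ndarray   # first nest propensity
    c1: np.ndarray    # first-attempt clutch size
    ns1: np.ndarray   # first-nest survival
    h: np.ndarray     # hatchability
    cs: np.ndarray    # chick survival to 50 days
    js: np.ndarray    # juvenile survival
    np2: np.ndarray   # renest propensity
    c2: np.ndarray    # second-attempt clutch size
    ns2: np.ndarray   # second-nest survival

    def __post_init__(self):
        for name in _PROB_STAGES:
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"stage {name} has draws outside [0, 1]")
        for name in ("c1", "c2"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if np.any(v < 0):
                raise ValueError(f"clutch size {name} has negative draws")


def fecundity(vitals: VitalRates) -> np.ndarray:
    """Per-draw fecundity g (female-equivalent eggs fledged per hen before
    the sex-ratio divisor)."""
    v = vitals
    first = v.np1 * v.c1 * v.ns1 * v.h * v.cs * v.js
    second = (1.0 - v.ns1) * v.np2 * v.c2 * v.ns2 * v.h * v.cs * v.js
    return first + second


def project(
    nt: np.ndarray,
    g: np.ndarray,
    jan: np.ndarray,
    age_structured: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """One-year projection and finite rate of change.

    ``nt``, ``g``, ``jan`` have age classes on the last axis (yearling,
    adult, ... ).  Recruits (``sum_a nt_a g_a / 2``) enter the first age
    class and survivors (``nt_a jan_a``) move up one class, the last class
    absorbing; ``age_structured=False`` applies the literal total-only
    recursion, returning the new total collapsed into a single class.

    Returns ``(nt_next, lambda_P)`` with ``lambda_P`` computed on
    age-summed totals.  A zero starting total makes the rate undefined.
    """
    nt = np.asarray(nt, dtype=float)
    g = np.asarray(g, dtype=float)
    jan = np.asarray(jan, dtype=float)
    if np.any(nt < 0):
        raise ValueError("abundances must be nonnegative")
    total = nt.sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("lambda_P undefined: zero total abundance")
    recruits = (nt * g).sum(axis=-1) / 2.0
    survivors = nt * jan
    if age_structured and nt.shape[-1] > 1:
        nt_next = np.zeros_like(nt)
        nt_next[..., 0] = recruits
        nt_next[..., 1:-1] = survivors[..., 0:-2]
        nt_next[..., -1] = survivors[..., -2] + survivors[..., -1]
    else:
        nt_next = (recruits + survivors.sum(axis=-1))[..., None]
    lam_p = nt_next.sum(axis=-1) / total
    return nt_next, lam_p


def impact_delta(lambda_before: np.ndarray, lambda_after: np.ndarray) -> np.ndarray:
    """Per-draw unrealised impact, before-minus-after finite rate of change
    (positive values mean development reduces growth)."""
    lb = np.asarray(lambda_before, dtype=float)
    la = np.asarray(lambda_after, dtype=float)
    if lb.shape != la.shape:
        raise ValueError("before/after draws must be matched in shape")
    return lb - la
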