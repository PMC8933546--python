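"""Lesion-level positivity call and reader-agreement statistics.

The clinical read-out of a fluctuation map is binary: does the lesion
contain a coloured (fluctuating) area or not?  The visual definition is
quantified here as a threshold rule: the call is positive when at least
``min_fraction`` of the valid lesion pixels reach ``level_threshold``
AND the largest 8-connected component of such pixels has at least
``min_component_px`` pixels (isolated speckled pixels do not read as a
"coloured area").

Default operating point: ``level_threshold = 32`` (fluctuation score
0.125).  The score of a lesion whose speckle field keeps per-frame
complex correlation rho is approximately 1 - rho**2, because the
one-frame-lag envelope correlation of an AR(1) field is close to
rho**2; level 32 therefore fires on any lesion losing more than about
12.5 % of its speckle correlation per frame interval (rho below about
0.93 at 20 fps), while static tissue with a realistic acquisition-noise
floor stays below level ~8.  All three parameters are explicit.

Agreement between the software call and a human reader over a cohort is
summarised by Cohen's kappa on the 2x2 contingency table, with the
Fleiss-Cohen-Everitt large-sample standard error and a Wald 95 % CI
(computed via statsmodels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateTableError, InputError
from .fluctuation import FluctuationMap

__all__ = [
    "LesionCall",
    "ContingencyTable2x2",
    "KappaResult",
    "classify_lesion",
    "cohen_kappa",
    "DEFAULT_LEVEL_THRESHOLD",
    "DEFAULT_MIN_FRACTION",
    "DEFAULT_MIN_COMPONENT_PX",
]

DEFAULT_LEVEL_THRESHOLD = 32
DEFAULT_MIN_FRACTION = 0.05
DEFAULT_MIN_COMPONENT_PX = 25

_CONN8 = np.ones((3, 3), dtype=int)


@dataclass
class LesionCall:
    positive: bool
    colored_fraction: float
    largest_component_px: int
    params: dict

    def to_json_dict(self) -> dict:
        return {
            "positive": bool(self.positive),
            "colored_fraction": float(self.colored_fraction),
            "largest_component_px": int(self.largest_component_px),
            "params": dict(self.params),
        }


@dataclass
class ContingencyTable2x2:
    """Counts for two binary raters: a = both positive, b = reference
    positive / test negative, c = reference negative / test positive,
    d = both negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise InputError(f"cell {name} must be a nonnegative integer, got {v}")
            setattr(self, name, int(v))
        if self.n < 1:
            raise InputError("contingency table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.float64)


@dataclass
class KappaResult:
    kappa: float
    se: float
    ci95: tuple[float, float]
    po: float
    pe: float

    def to_json_dict(self) -> dict:
        return {"kappa": self.kappa, "se": self.se,
                "ci95": list(self.ci95), "po": self.po, "pe": self.pe}


def classify_lesion(fmap: FluctuationMap, lesion_mask: np.ndarray,
                    level_threshold: int = DEFAULT_LEVEL_THRESHOLD,
                    min_fraction: float = DEFAULT_MIN_FRACTION,
                    min_component_px: int = DEFAULT_MIN_COMPONENT_PX) -> LesionCall:
    """Binary fluttering call for a lesion region of a fluctuation map."""
    if not 0 <= level_threshold <= 255:
        raise InputError(f"level_threshold must lie in 0-255, got {level_threshold}")
    if not 0.0 <= min_fraction <= 1.0:
        raise InputError(f"min_fraction must lie in [0, 1], got {min_fraction}")
    lesion = np.asarray(lesion_mask, dtype=bool)
    if lesion.shape != fmap.level.shape:
        raise InputError("lesion mask shape does not match the map")
    support = lesion & fmap.valid
    n_support = int(support.sum())
    if n_support == 0:
        raise InputError("lesion mask has no valid analysed pixels")
    colored = support & (fmap.level >= level_threshold)
    fraction = float(colored.sum()) / n_support
    if colored.any():
        labels, n_comp = ndimage.label(colored, structure=_CONN8)
        largest = int(np.bincount(labels.ravel())[1:].max())
    else:
        largest = 0
    positive = (fraction >= min_fraction) and (largest >= min_component_px)
    return LesionCall(positive, fraction, largest,
                      {"level_threshold": int(level_threshold),
                       "min_fraction": float(min_fraction),
                       "min_component_px": int(min_component_px),
                       "n_valid_lesion_px": n_support})


def cohen_kappa(table: ContingencyTable2x2) -> KappaResult:
    """Cohen's kappa with Fleiss-Cohen-Everitt SE and Wald 95 % CI.

    po = (a + d) / n, pe from the marginal products, kappa =
    (po - pe) / (1 - pe).  The CI is kappa +/- 1.96 se, truncated to
    [-1, 1].  Degenerate marginals (pe = 1) make kappa undefined and
    raise :class:`DegenerateTableError`.
    """
    n = table.n
    po = (table.a + table.d) / n
    pe = ((table.a + table.b) * (table.a + table.c)
          + (table.c + table.d) * (table.b + table.d)) / n ** 2
    if abs(1.0 - pe) < 1e-12:
        raise DegenerateTableError(
            "chance agreement pe = 1 (all observations in one margin); kappa undefined")

    from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa

    res = _sm_kappa(table.as_array(), return_results=True)
    kappa = float(res.kappa)
    se = float(np.sqrt(max(float(res.var_kappa), 0.0)))  # guard fp-negative variance
    lo = max(-1.0, kappa - 1.96 * se)
    hi = min(1.0, kappa + 1.96 * se)
    return KappaResult(kappa, se, (lo, hi), float(po), float(pe))
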