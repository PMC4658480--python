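"""From per-proton melting temperatures to a folding-event hierarchy.

Two complementary groupings are provided.  The supervised path
(:func:`group_tms`) summarises Tms inside user-supplied structural classes
(strand / turn / tryptophan, say) with a Gaussian summary and a normality
check.  The blind path (:func:`detect_events`) fits one-dimensional Gaussian
mixtures for k = 1..k_max and picks k by BIC — used, e.g., to show that a
destabilised mutant melts in a single event.  Events ordered by descending
mean Tm give the folding sequence: on cooling, the element with the highest
Tm forms first.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .meltfit import MeltFit
from .types import ProtonID

__all__ = [
    "TmEvent",
    "FoldingSequence",
    "group_tms",
    "detect_events",
    "folding_sequence",
    "TmLandscape",
]

logger = logging.getLogger(__name__)

# variance floor for degenerate (all-equal) mixture components, K^2
_VARIANCE_FLOOR = 1e-4


@dataclass(frozen=True)
class TmEvent:
    """A group of protons melting together, with its Gaussian Tm summary."""

    label: str
    members: Tuple[Tuple[ProtonID, float], ...]   # (proton, Tm)
    mean_tm: float
    sd_tm: float
    shapiro_stat: Optional[float] = None
    shapiro_p: Optional[float] = None
    qq_correlation: Optional[float] = None

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def sem(self) -> float:
        return self.sd_tm / np.sqrt(self.n) if self.n else np.nan


@dataclass(frozen=True)
class FoldingSequence:
    """Events ordered by descending mean Tm (= order of formation on cooling).

    ``separations[i]`` annotates the gap between events i and i+1:
    (delta_mean, combined_sd, flag) where the flag is ``"successive"`` when
    |Δmean| exceeds the sum of the two SDs and ``"superimposed"`` otherwise.
    """

    events: Tuple[TmEvent, ...]
    separations: Tuple[Tuple[float, float, str], ...]

    def order(self) -> List[str]:
        return [e.label for e in self.events]

    def summary(self) -> str:
        lines = ["Folding sequence (first-forming event on cooling first):"]
        for i, e in enumerate(self.events):
            lines.append(
                f"  {i + 1}. {e.label:>8}  Tm = {e.mean_tm:7.2f} +/- {e.sd_tm:.2f} K"
                f"  (n={e.n})"
            )
            if i < len(self.separations):
                d, c, flag = self.separations[i]
                lines.append(f"       |dTm| = {d:.2f} K vs combined SD {c:.2f} K"
                             f" -> {flag}")
        return "\n".join(lines)


def _normality(tms: np.ndarray):
    """Shapiro-Wilk plus QQ correlation; undefined below n = 3 or at SD 0."""
    if len(tms) < 3 or np.std(tms) == 0:
        return None, None, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.shapiro(tms)
    osm, osr = stats.probplot(tms, dist="norm", fit=False)
    qq = float(np.corrcoef(osm, osr)[0, 1])
    return float(stat), float(p), qq


ClassMap = Union[Mapping[ProtonID, str], Callable[[ProtonID], Optional[str]]]


def group_tms(
    fits: Iterable[MeltFit],
    class_map: ClassMap,
    unmapped: str = "error",
) -> List[TmEvent]:
    """Group fitted Tms by structural class and summarise each class.

    Per class the unweighted mean, the unbiased SD and a normality summary
    of the member Tms are reported.  ``unmapped`` controls what happens to
    protons missing from the class map: ``"error"`` raises, ``"other"``
    collects them under the label ``other``, ``"drop"`` skips them.
    Output is invariant to input order (classes sorted by label, members by
    proton).
    """
    lookup = class_map if callable(class_map) else class_map.get
    groups: Dict[str, List[Tuple[ProtonID, float]]] = {}
    for f in fits:
        label = lookup(f.proton)
        if label is None:
            if unmapped == "error":
                raise KeyError(f"proton {f.proton} missing from the class map")
            if unmapped == "drop":
                continue
            label = "other"
        groups.setdefault(label, []).append((f.proton, float(f.tm)))
    events: List[TmEvent] = []
    for label in sorted(groups):
        members = sorted(groups[label], key=lambda m: m[0])
        if not members:
            logger.warning("class %r empty after filtering; event dropped", label)
            continue
        tms = np.array([tm for _, tm in members])
        sd = float(np.std(tms, ddof=1)) if len(tms) > 1 else 0.0
        stat, p, qq = _normality(tms)
        events.append(TmEvent(label, tuple(members), float(np.mean(tms)), sd,
                              stat, p, qq))
    return events


def detect_events(
    tms: Sequence[float],
    k_max: int = 4,
    seed: int = 0,
    n_init: int = 10,
) -> Tuple[int, List[Tuple[float, float, float]]]:
    """Blind Gaussian-mixture event detection on a set of Tm values.

    Fits 1-D Gaussian mixtures for k = 1..k_max (10 seeded restarts each,
    variance floor 1e-4 K²) and selects k by BIC.  Returns the selected k
    and the components as (mean, sd, weight) sorted by descending mean.
    Deterministic for a fixed seed and invariant to input permutation.
    """
    x = np.sort(np.asarray(tms, dtype=float))[:, None]
    if len(x) < 4:
        raise ValueError(f"need >= 4 Tm values, got {len(x)}")
    if k_max < 1 or k_max > 4:
        raise ValueError("k_max must be in 1..4")
    best_k, best_bic, best_gm = 1, np.inf, None
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", reg_covar=_VARIANCE_FLOOR,
            n_init=n_init, random_state=seed, max_iter=500,
        )
        with warnings.catch_warnings():
            # k > number of distinct values is a legitimate candidate that
            # the BIC will discard; sklearn warns about the degeneracy
            warnings.simplefilter("ignore")
            gm.fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:
            best_k, best_bic, best_gm = k, bic, gm
    comps = [
        (float(m[0]), float(np.sqrt(c[0, 0])), float(w))
        for m, c, w in zip(best_gm.means_, best_gm.covariances_, best_gm.weights_)
    ]
    comps.sort(key=lambda t: -t[0])
    return best_k, comps


def folding_sequence(events: Sequence[TmEvent]) -> FoldingSequence:
    """Order events into a folding sequence (descending mean Tm).

    Ties are broken lexicographically by label.  Adjacent events are flagged
    ``"successive"`` when their mean separation exceeds the sum of their SDs
    and ``"superimposed"`` when the Gaussians overlap within that band.
    """
    if not events:
        raise ValueError("need at least one event")
    ordered = tuple(sorted(events, key=lambda e: (-e.mean_tm, e.label)))
    seps = []
    for a, b in zip(ordered, ordered[1:]):
        delta = abs(a.mean_tm - b.mean_tm)
        combined = a.sd_tm + b.sd_tm
        seps.append((delta, combined, "successive" if delta > combined
                     else "superimposed"))
    return FoldingSequence(ordered, tuple(seps))


class TmLandscape:
    """Model object bundling the grouped and blind views of a Tm set.

    ``TmLandscape(fits, class_map).fit()`` returns a
    :class:`LandscapeResult` holding the per-class events, the folding
    sequence, and the blind mixture selection on the pooled Tms.
    """

    def __init__(self, fits: Sequence[MeltFit], class_map: ClassMap,
                 unmapped: str = "error"):
        self.fits = list(fits)
        self.class_map = class_map
        self.unmapped = unmapped

    def fit(self, k_max: int = 4, seed: int = 0) -> "LandscapeResult":
        events = group_tms(self.fits, self.class_map, self.unmapped)
        seq = folding_sequence(events)
        tms = [f.tm for f in self.fits]
        k, comps = detect_events(tms, k_max=k_max, seed=seed) if len(tms) >= 4 \
            else (len(events), [])
        return LandscapeResult(tuple(events), seq, k, tuple(comps))


@dataclass(frozen=True)
class LandscapeResult:
    events: Tuple[TmEvent, ...]
    sequence: FoldingSequence
    k_selected: int
    components: Tuple[Tuple[float, float, float], ...]

    def summary(self) -> str:
        lines = [self.sequence.summary(),
                 f"Blind mixture selection: k = {self.k_selected}"]
        for m, s, w in self.components:
            lines.append(f"  component: mean {m:7.2f} K, sd {s:.2f} K, weight {w:.2f}")
        return "\n".join(lines)
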