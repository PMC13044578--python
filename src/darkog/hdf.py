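"""Homology-detection-failure (HDF) inference from bitscore decay.

The model: the best homology-search bitscore between a family's
representative sequence and a homolog in another dataset decays
approximately exponentially with the evolutionary (patristic) distance d
between the two datasets,

    B(d) = a * exp(-b * d) + noise,

with a > 0 the bitscore at zero distance and b >= 0 the decay rate per
substitution/site.  Fitting (a, b) to the datasets where a homolog *is*
present lets us ask, for a dataset where no homolog was found, how likely
it is that a true homolog would have scored below the detectability floor
— i.e. that its absence is a homology *detection* failure rather than a
true absence.

The detectability floor is the Karlin–Altschul bitscore at which a hit
would just reach the search e-value threshold E in a search space of size
m*n:  B_thr = log2(m * n / E).  The predictive distribution of the true
bitscore at distance d* is taken as Gaussian around a*exp(-b*d*) with
variance equal to the fit's residual variance plus first-order (delta
method) propagation of the parameter covariance; P(B < B_thr) is the HDF
probability for that dataset.

Per family, probabilities for datasets *outside* the family's LCA clade
are classified as supporting HDF (p > 0.95), contradicting it (p < 0.05),
or ambiguous, and the family-level call requires >= 50% of the scored
non-LCA datasets on one side.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from darkog.types import Orthogroup, ProteinRef

logger = logging.getLogger(__name__)

SUPPORT_THRESHOLD = 0.95
AGAINST_THRESHOLD = 0.05
CALL_FRACTION = 0.5
DEFAULT_E_THRESHOLD = 1e-3


class HdfCall(str, enum.Enum):
    hdf_supported = "hdf_supported"
    hdf_rejected = "hdf_rejected"
    ambiguous = "ambiguous"


@dataclass(frozen=True)
class BitscoreObservation:
    """Best bitscore of one dataset's proteins against the representative."""

    og_id: str
    dataset_id: str
    distance: float
    bitscore: float
    rep_length: int = 1

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if self.bitscore <= 0:
            raise ValueError("observed homolog bitscore must be > 0")


@dataclass
class DecayFit:
    """Fitted exponential bitscore-decay model for one family."""

    a: float
    b: float
    residual_sd: float
    covariance: np.ndarray
    n_points: int

    def predict(self, d: float | np.ndarray) -> float | np.ndarray:
        return self.a * np.exp(-self.b * np.asarray(d, dtype=float))


@dataclass
class HdfAssessment:
    """Per-family HDF evidence summary over non-LCA datasets."""

    og_id: str
    probabilities: dict[str, float]
    support: int
    against: int
    ambiguous: int
    og_call: HdfCall
    inside_lca_absent: dict[str, float] = field(default_factory=dict)
    not_scorable: bool = False

    @property
    def n_scored(self) -> int:
        return self.support + self.against + self.ambiguous


def best_bitscore_per_dataset(
    og: Orthogroup,
    within_og_scores: Mapping[ProteinRef, float],
    distances: Mapping[str, float],
) -> list[BitscoreObservation]:
    """One observation per member dataset: max score vs the representative.

    ``within_og_scores`` maps each member protein to its bitscore against
    the representative (paralogs collapse to the per-dataset max); the
    representative's own dataset contributes the d=0 anchor.
    """
    if og.representative is None:
        raise ValueError(f"orthogroup {og.og_id} has no representative set")
    best: dict[str, float] = {}
    for member, score in within_og_scores.items():
        if member not in og.members:
            continue
        cur = best.get(member.dataset_id)
        if cur is None or score > cur:
            best[member.dataset_id] = score
    rep_len = og.representative.length or 1
    obs = []
    for dataset_id, score in sorted(best.items()):
        if dataset_id not in distances:
            raise KeyError(f"no tree distance for dataset {dataset_id}")
        obs.append(
            BitscoreObservation(
                og_id=og.og_id,
                dataset_id=dataset_id,
                distance=distances[dataset_id],
                bitscore=score,
                rep_length=rep_len,
            )
        )
    return obs


def fit_decay(obs: Sequence[BitscoreObservation]) -> DecayFit:
    """Nonlinear least squares fit of B(d) = a * exp(-b * d).

    Requires >= 3 observations spanning >= 2 distinct distances.  The
    residual standard deviation uses n-2 degrees of freedom; the parameter
    covariance comes from the NLS Jacobian scaled by the residual variance.
    """
    if len(obs) < 3:
        raise ValueError(f"underdetermined: need >= 3 observations, got {len(obs)}")
    d = np.array([o.distance for o in obs], dtype=float)
    B = np.array([o.bitscore for o in obs], dtype=float)
    if len(np.unique(d)) < 2:
        raise ValueError("underdetermined: all observations at the same distance")

    def model(x, a, b):
        return a * np.exp(-b * x)

    # initial guess: a from the nearest points, b from a log-linear slope
    a0 = float(max(B.max(), 1.0))
    with np.errstate(divide="ignore"):
        logB = np.log(np.clip(B, 1e-9, None))
    slope = np.polyfit(d, logB, 1)[0] if len(np.unique(d)) > 1 else 0.0
    b0 = float(max(-slope, 0.0))
    try:
        popt, pcov = optimize.curve_fit(
            model, d, B, p0=(a0, b0),
            bounds=([1e-9, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"decay fit did not converge for {obs[0].og_id} "
            f"(n={len(obs)}, d range {d.min():.3g}-{d.max():.3g}): {exc}"
        ) from exc
    resid = B - model(d, *popt)
    dof = max(len(obs) - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    if not np.all(np.isfinite(pcov)):
        pcov = np.zeros((2, 2))
    return DecayFit(
        a=float(popt[0]),
        b=float(popt[1]),
        residual_sd=residual_sd,
        covariance=np.asarray(pcov, dtype=float),
        n_points=len(obs),
    )


def bitscore_floor(rep_length: int, db_length: int, e_threshold: float) -> float:
    """Karlin–Altschul bitscore at which a hit reaches the e-value threshold."""
    if e_threshold <= 0:
        raise ValueError("e_threshold must be > 0 (a zero threshold puts the "
                         "detection floor at infinity)")
    if rep_length < 1 or db_length < 1:
        raise ValueError("search-space lengths must be >= 1")
    return float(np.log2(rep_length * db_length / e_threshold))


def predict_undetected(
    fit: DecayFit,
    d_star: float,
    search_space: tuple[int, int],
    e_threshold: float = DEFAULT_E_THRESHOLD,
) -> float:
    """P(true homolog at distance d_star scores below the detection floor).

    The predictive bitscore distribution is Gaussian with mean
    a*exp(-b*d_star) and variance = residual variance + delta-method
    propagation of the (a, b) covariance through the gradient
    [exp(-b d), -a d exp(-b d)].
    """
    if d_star < 0:
        raise ValueError("d_star must be >= 0")
    rep_length, db_length = search_space
    b_thr = bitscore_floor(rep_length, db_length, e_threshold)
    mean = fit.a * np.exp(-fit.b * d_star)
    grad = np.array([np.exp(-fit.b * d_star), -fit.a * d_star * np.exp(-fit.b * d_star)])
    param_var = float(grad @ fit.covariance @ grad)
    var = fit.residual_sd**2 + max(param_var, 0.0)
    if var <= 0:
        return float(mean < b_thr)
    p = stats.norm.cdf(b_thr, loc=mean, scale=np.sqrt(var))
    return float(min(max(p, 0.0), 1.0))


def classify_probability(p: float) -> str:
    if p > SUPPORT_THRESHOLD:
        return "support"
    if p < AGAINST_THRESHOLD:
        return "against"
    return "ambiguous"


def assess_og(
    og: Orthogroup,
    predictions: Mapping[str, float],
    lca_datasets: Iterable[str],
) -> HdfAssessment:
    """Aggregate per-dataset HDF probabilities into a family-level call.

    ``predictions`` maps each dataset *absent* from the OG to its HDF
    probability; ``lca_datasets`` is the set of datasets inside the OG's
    LCA clade.  Only predictions for datasets outside the LCA enter the
    call; inside-LCA absences (possibly incomplete datasets) are reported
    separately.  The call is supported/rejected when >= 50% of the scored
    non-LCA datasets fall in the corresponding class, else ambiguous.
    """
    lca_set = set(lca_datasets)
    outside: dict[str, float] = {}
    inside: dict[str, float] = {}
    for dataset_id, p in predictions.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability out of range for {dataset_id}: {p}")
        (inside if dataset_id in lca_set else outside)[dataset_id] = p
    counts = {"support": 0, "against": 0, "ambiguous": 0}
    for p in outside.values():
        counts[classify_probability(p)] += 1
    n = sum(counts.values())
    if n == 0:
        return HdfAssessment(
            og_id=og.og_id, probabilities=outside,
            support=0, against=0, ambiguous=0,
            og_call=HdfCall.ambiguous, inside_lca_absent=inside,
            not_scorable=True,
        )
    if counts["support"] >= CALL_FRACTION * n:
        call = HdfCall.hdf_supported
    elif counts["against"] >= CALL_FRACTION * n:
        call = HdfCall.hdf_rejected
    else:
        call = HdfCall.ambiguous
    return HdfAssessment(
        og_id=og.og_id,
        probabilities=outside,
        support=counts["support"],
        against=counts["against"],
        ambiguous=counts["ambiguous"],
        og_call=call,
        inside_lca_absent=inside,
    )
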