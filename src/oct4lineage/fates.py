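"""Endpoint fate classification and pro-fate propagation.

After the differentiation stimulus, each surviving cell's final-frame
(OCT4, CDX2) intensities place it in one of two populations:
self-renewing (OCT4+/CDX2-) or differentiated (OCT4-/CDX2+).  A
two-component full-covariance Gaussian mixture is fitted to the joint
intensities; ``p_diff`` is the posterior probability of the
differentiated component, and only confident calls (p_diff < 0.01 or
p_diff > 0.99 by default) are classified.  Pro-fate labels are then
propagated up the lineage: an ancestor is pro-self or pro-differentiated
when all of its classified terminal descendants share that class,
pro-mixed when both classes occur, and undetermined when none of its
terminal descendants were classified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

from .lineage import LineageForest, sister_pairs

__all__ = [
    "MixtureModel",
    "FateCall",
    "fit_endpoint_mixture",
    "assign_fate",
    "propagate_profate",
    "sister_fate_concordance",
]

SELF_RENEWING = "self_renewing"
DIFFERENTIATED = "differentiated"
UNCLASSIFIED = "unclassified"

PRO_SELF = "pro_self"
PRO_DIFF = "pro_diff"
PRO_MIXED = "pro_mixed"
UNDETERMINED = "undetermined"


@dataclass
class MixtureModel:
    """Two-component Gaussian mixture over (OCT4, CDX2) endpoint space."""

    weights: np.ndarray  # (2,)
    means: np.ndarray  # (2, 2): rows = components, cols = (oct4, cdx2)
    covariances: np.ndarray  # (2, 2, 2)
    diff_component: int  # index of the OCT4-low / CDX2-high component
    log_transformed: bool = False

    def posterior_diff(self, oct4: np.ndarray, cdx2: np.ndarray) -> np.ndarray:
        """P(differentiated component | point) for each endpoint."""
        x = np.column_stack([np.asarray(oct4, float), np.asarray(cdx2, float)])
        if self.log_transformed:
            x = np.log10(np.maximum(x, 1e-9))
        logp = np.empty((len(x), 2))
        for k in range(2):
            logp[:, k] = np.log(self.weights[k]) + multivariate_normal.logpdf(
                x, mean=self.means[k], cov=self.covariances[k]
            )
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        p /= p.sum(axis=1, keepdims=True)
        return p[:, self.diff_component]

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "means": self.means.tolist(),
                "covariances": self.covariances.tolist(),
                "diff_component": int(self.diff_component),
                "log_transformed": self.log_transformed,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "MixtureModel":
        d = json.loads(text)
        return cls(
            weights=np.array(d["weights"]),
            means=np.array(d["means"]),
            covariances=np.array(d["covariances"]),
            diff_component=int(d["diff_component"]),
            log_transformed=bool(d.get("log_transformed", False)),
        )


@dataclass(frozen=True)
class FateCall:
    cell_id: str
    p_diff: float
    endpoint_class: str  # self_renewing | differentiated | unclassified


def fit_endpoint_mixture(
    endpoints: pd.DataFrame,
    *,
    log10: bool = False,
    seed: int = 0,
    n_restarts: int = 10,
) -> MixtureModel:
    """EM-fit the two-component endpoint mixture.

    ``endpoints`` needs columns ``oct4_afu`` and ``cdx2_afu``.  The fit
    uses k-means initialization with ``n_restarts`` seeded restarts,
    keeping the best log-likelihood, so it is deterministic given the
    seed.  The differentiated component must have both the lower OCT4
    mean and the higher CDX2 mean; ambiguous geometry is an error, not a
    guess.
    """
    x = endpoints[["oct4_afu", "cdx2_afu"]].to_numpy(dtype=float)
    if log10:
        x = np.log10(np.maximum(x, 1e-9))
    if len(x) < 4 or np.allclose(x, x[0]):
        raise ValueError("endpoint data degenerate: need >=2 distinct points per component")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_restarts,
        init_params="kmeans",
        random_state=seed,
        reg_covar=1e-6,
    ).fit(x)
    means = gm.means_
    lo_oct4 = int(np.argmin(means[:, 0]))
    hi_cdx2 = int(np.argmax(means[:, 1]))
    if lo_oct4 != hi_cdx2:
        raise ValueError(
            "component identification ambiguous: one component is higher in "
            f"both channels (means={means.tolist()}); cannot map components "
            "to self-renewing vs differentiated"
        )
    return MixtureModel(
        weights=gm.weights_.copy(),
        means=means.copy(),
        covariances=gm.covariances_.copy(),
        diff_component=lo_oct4,
        log_transformed=log10,
    )


def assign_fate(
    endpoints: pd.DataFrame,
    model: MixtureModel,
    *,
    lower: float = 0.01,
    upper: float = 0.99,
) -> dict[str, FateCall]:
    """Posterior-threshold classification of endpoint cells.

    Cells with ``p_diff`` between the thresholds remain unclassified
    (the gray dots of the endpoint scatter) and are excluded downstream.
    """
    p = model.posterior_diff(
        endpoints["oct4_afu"].to_numpy(), endpoints["cdx2_afu"].to_numpy()
    )
    out = {}
    for cid, pd_i in zip(endpoints["cell_id"].astype(str), p):
        if pd_i > upper:
            cls = DIFFERENTIATED
        elif pd_i < lower:
            cls = SELF_RENEWING
        else:
            cls = UNCLASSIFIED
        out[cid] = FateCall(cid, float(pd_i), cls)
    return out


def propagate_profate(
    forest: LineageForest, fate_calls: dict[str, FateCall]
) -> dict[str, str]:
    """Back-propagate endpoint classes into pro-fate labels for every cell.

    Bottom-up over the forest: each cell's label summarizes the classes
    of its classified terminal (leaf) descendants.  A classified leaf
    carries its own class as its pro-fate.
    """
    labels: dict[str, str] = {}

    def classes_under(cid: str) -> set[str]:
        kids = forest.children_of(cid)
        if not kids:
            call = fate_calls.get(cid)
            if call is None or call.endpoint_class == UNCLASSIFIED:
                return set()
            return {call.endpoint_class}
        found: set[str] = set()
        for k in kids:
            found |= _memo[k]
        return found

    _memo: dict[str, set[str]] = {}
    # post-order iteration
    for root in forest.roots:
        stack = [(root, False)]
        while stack:
            cid, expanded = stack.pop()
            kids = forest.children_of(cid)
            if kids and not expanded:
                stack.append((cid, True))
                stack.extend((k, False) for k in kids)
            else:
                _memo[cid] = classes_under(cid)

    for cid, found in _memo.items():
        if not found:
            labels[cid] = UNDETERMINED
        elif found == {SELF_RENEWING}:
            labels[cid] = PRO_SELF
        elif found == {DIFFERENTIATED}:
            labels[cid] = PRO_DIFF
        else:
            labels[cid] = PRO_MIXED
    return labels


def sister_fate_concordance(
    forest: LineageForest, fate_calls: dict[str, FateCall]
) -> float | None:
    """Fraction of classified sister pairs choosing the same endpoint fate.

    Pairs where either sister is unclassified (or unmeasured) are
    excluded from the denominator.  Returns None with no eligible pair.
    """
    n = same = 0
    for a, b in sister_pairs(forest):
        ca, cb = fate_calls.get(a), fate_calls.get(b)
        if ca is None or cb is None:
            continue
        if UNCLASSIFIED in (ca.endpoint_class, cb.endpoint_class):
            continue
        n += 1
        same += ca.endpoint_class == cb.endpoint_class
    return same / n if n else None
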