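"""Profile similarity and affected-step inference.

A knockdown's RAMP profile is a phenotype signature: factors acting at the
same processing steps produce similar sign patterns, and the direction of
individual ratios identifies which steps are inhibited.  This module
formalizes both readings.

Distances
---------
Profiles are compared entrywise over their shared non-missing ratios with
Pearson correlation, cosine similarity, or sign concordance (fraction of
entries whose thresholded signs agree).  Hierarchical clustering with
average linkage over ``1 - pearson`` groups factors into phenotype classes.

Step inference
--------------
At steady state of a first-order processing network, the knockdown-vs-
reference shift of every panel ratio is a signed sum of the per-step
log2 inhibition factors (flux conservation makes each /PTP ratio report
the branch share feeding the species divided by its own consumption rate;
product/substrate ratios compare the two consumption rates).  The default
mouse panel over-determines the six panel-covered steps (2b, 2c, A0,
site 1, ITS2/4b, late 18SE maturation) plus one free term for the shared
downstream flux, so the per-step log2 inhibitions are estimated by least
squares over all non-missing entries and thresholded at ``theta``.  A
product/substrate ratio is thereby read in both directions, exactly as in
visual RAMP interpretation: 29S/34S down means A0 cleavage is slow
relative to site 1; 29S/34S up means site 1 is slow relative to A0 (29S
accumulates because its consumer is blocked).

The branch-choice ratio 34S/36S additionally yields an explicitly
*relative* verdict (site 2b inhibited relative to 2c, or vice versa);
single profiles cannot distinguish absolute rate changes that affect both
routes equally.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .pathway import PathwayGraph
from .ramp import RAMPProfile

__all__ = [
    "Metric",
    "ProfileDistance",
    "Verdict",
    "StepEvidence",
    "ComparisonError",
    "DEFAULT_THETA",
    "PANEL_COVERED_TAGS",
    "profile_distance",
    "sign_concordance",
    "cluster_profiles",
    "infer_affected_steps",
    "inhibited_tags",
]

#: minimal interpretable shift: a 1.5-fold change
DEFAULT_THETA = math.log2(1.5)


class ComparisonError(ValueError):
    """Too little shared information to compare profiles."""


class Metric(str, enum.Enum):
    PEARSON = "pearson_on_log_ratios"
    COSINE = "cosine"
    SIGN_CONCORDANCE = "sign_concordance"


@dataclass(frozen=True)
class ProfileDistance:
    metric: Metric
    value: float
    n_shared: int


class Verdict(str, enum.Enum):
    INHIBITED = "inhibited"
    STIMULATED = "stimulated"
    UNCHANGED = "unchanged"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class StepEvidence:
    """Verdict for one processing step (factor tag) or the branch choice.

    ``score`` lies in [-1, 1]: the estimated log2 shift clipped at two
    thresholds; negative means inhibition.
    """

    target: str
    verdict: Verdict
    score: float
    supporting: tuple[str, ...] = ()


def _shared(p1: RAMPProfile, p2: RAMPProfile) -> tuple[np.ndarray, np.ndarray]:
    if p1.panel.labels != p2.panel.labels:
        raise ComparisonError("profiles are over different panels")
    v1, v2 = p1.values(), p2.values()
    mask = ~(np.isnan(v1) | np.isnan(v2))
    return v1[mask], v2[mask]


def sign_concordance(p1: RAMPProfile, p2: RAMPProfile, theta: float = 0.0) -> float:
    """Fraction of shared entries with equal thresholded sign.

    Entries with ``|value| <= theta`` count as sign 0.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    v1, v2 = _shared(p1, p2)
    if len(v1) == 0:
        raise ComparisonError("no shared non-missing entries")
    s1 = np.where(np.abs(v1) <= theta, 0, np.sign(v1))
    s2 = np.where(np.abs(v2) <= theta, 0, np.sign(v2))
    return float(np.mean(s1 == s2))


def profile_distance(
    p1: RAMPProfile, p2: RAMPProfile, metric: Metric = Metric.PEARSON, theta: float = 0.0
) -> ProfileDistance:
    """Similarity between two profiles over shared non-missing entries."""
    metric = Metric(metric)
    v1, v2 = _shared(p1, p2)
    if len(v1) < 3:
        raise ComparisonError(
            f"only {len(v1)} shared non-missing entries; need at least 3"
        )
    if metric is Metric.PEARSON:
        if np.ptp(v1) == 0 or np.ptp(v2) == 0:
            raise ComparisonError("constant profile: Pearson correlation undefined")
        value = float(np.corrcoef(v1, v2)[0, 1])
    elif metric is Metric.COSINE:
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 == 0 or n2 == 0:
            raise ComparisonError("zero profile: cosine similarity undefined")
        value = float(np.dot(v1, v2) / (n1 * n2))
    else:
        value = sign_concordance(p1, p2, theta)
    return ProfileDistance(metric, value, len(v1))


def cluster_profiles(
    profiles: list[RAMPProfile], labels: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative average-linkage tree over profiles.

    Dissimilarity is ``1 - pearson``.  Profiles are ordered by label before
    clustering so the result is deterministic regardless of input order.
    Returns a scipy linkage matrix together with the sorted labels (leaf i
    of the linkage matrix is ``labels[i]``).
    """
    if len(profiles) < 2:
        raise ComparisonError("need at least two profiles to cluster")
    if labels is None:
        labels = [p.metadata.get("factor", f"profile-{i}") for i, p in enumerate(profiles)]
    if len(labels) != len(profiles) or len(set(labels)) != len(labels):
        raise ComparisonError("profile labels must be unique")
    order = np.argsort(labels, kind="stable")
    profiles = [profiles[i] for i in order]
    labels = [labels[i] for i in order]
    m = len(profiles)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            try:
                d = 1.0 - profile_distance(profiles[i], profiles[j], Metric.PEARSON).value
            except ComparisonError as exc:
                raise ComparisonError(
                    f"pair ({labels[i]}, {labels[j]}) cannot be compared: {exc}"
                ) from exc
            dist[i, j] = dist[j, i] = d
    return linkage(squareform(dist, checks=False), method="average"), labels


# ---------------------------------------------------------------------------
# affected-step inference over the default mouse panel

#: factor tags whose steps are covered by ratios of the default panel
PANEL_COVERED_TAGS: tuple[str, ...] = ("2b", "2c", "SSU-A0", "site1", "ITS2", "late-18SE")

_FLUX = "_lsu_flux_share"  # free nuisance term: log2 change of total separated flux

#: steady-state coefficients: Delta log2 of each panel entry as a signed sum
#: of per-tag log2 inhibition factors (see module docstring)
_COEFFS: dict[str, dict[str, float]] = {
    "34S/PTP": {"2c": 1, "SSU-A0": -1},
    "36S/PTP": {"2b": 1, "2c": -1},
    "29S/PTP": {"2c": 1, "site1": -1},
    "20S/PTP": {"2c": 1, "2b": -1},
    "19S/PTP": {"2c": 1},
    "18SE/PTP": {"late-18SE": -1, _FLUX: 1},
    "32S/PTP": {"ITS2": -1, _FLUX: 1},
    "12S/PTP": {_FLUX: 1},
    "34S/36S": {"2c": 2, "SSU-A0": -1, "2b": -1},
    "29S/34S": {"SSU-A0": 1, "site1": -1},
    "20S/34S": {"SSU-A0": 1, "2b": -1},
    "18SE/34S": {_FLUX: 1, "late-18SE": -1, "2c": -1, "SSU-A0": 1},
    "18SE/20S": {_FLUX: 1, "late-18SE": -1, "2c": -1, "2b": 1},
    "32S/36S": {_FLUX: 1, "ITS2": -1, "2b": -1, "2c": 1},
    "12S/32S": {"ITS2": 1},
}


def _verdict(u: float, theta: float) -> Verdict:
    if u < -theta:
        return Verdict.INHIBITED
    if u > theta:
        return Verdict.STIMULATED
    return Verdict.UNCHANGED


def infer_affected_steps(
    profile: RAMPProfile,
    graph: PathwayGraph | None = None,
    theta: float = DEFAULT_THETA,
) -> list[StepEvidence]:
    """Infer which processing steps a knockdown profile implicates.

    Requires the default mouse panel.  Estimates the log2 inhibition of
    each panel-covered step by least squares over the non-missing entries,
    then applies the threshold ``theta`` (default log2 1.5): estimates
    below ``-theta`` give an *inhibited* verdict, above ``+theta``
    *stimulated*, otherwise *unchanged*.  A step whose inhibition is not
    identifiable from the available entries is *indeterminate*.  The
    returned list ends with the relative branch-choice verdict read
    directly from 34S/36S (positive shift: 2b inhibited relative to 2c).
    """
    unknown = [lab for lab in profile.panel.labels if lab not in _COEFFS]
    if unknown:
        raise ValueError(
            f"inference requires the default mouse panel; unexpected ratios {unknown}"
        )
    if graph is not None:
        tags = graph.factor_tags()
        for t in PANEL_COVERED_TAGS:
            if t not in tags:
                raise ValueError(f"pathway graph lacks expected factor tag {t!r}")

    params = list(PANEL_COVERED_TAGS) + [_FLUX]
    rows, y, labels = [], [], []
    for e in profile.entries:
        if e.value is None:
            continue
        coeff = _COEFFS[e.definition.label]
        rows.append([float(coeff.get(p, 0.0)) for p in params])
        y.append(e.value)
        labels.append(e.definition.label)

    out: list[StepEvidence] = []
    if rows:
        a = np.asarray(rows)
        yv = np.asarray(y)
        rank_a = np.linalg.matrix_rank(a, tol=1e-9)
        u, *_ = np.linalg.lstsq(a, yv, rcond=None)
    else:
        a = np.zeros((0, len(params)))
        yv = np.zeros(0)
        rank_a = 0
        u = np.zeros(len(params))

    for j, tag in enumerate(PANEL_COVERED_TAGS):
        support = tuple(
            lab for lab, row in zip(labels, rows) if row[j] != 0.0
        )
        e_j = np.zeros((1, len(params)))
        e_j[0, j] = 1.0
        identifiable = (
            len(rows) > 0
            and np.linalg.matrix_rank(np.vstack([a, e_j]), tol=1e-9) == rank_a
        )
        if not identifiable:
            out.append(StepEvidence(tag, Verdict.INDETERMINATE, 0.0, support))
            continue
        est = float(u[j])
        score = float(np.clip(est / (2 * theta), -1.0, 1.0))
        out.append(StepEvidence(tag, _verdict(est, theta), score, support))

    # relative 2b-vs-2c branch verdict straight off the mutually exclusive ratio
    try:
        branch = profile.value("34S/36S")
    except KeyError:  # pragma: no cover - panel check above guarantees presence
        branch = None
    if branch is None:
        out.append(StepEvidence("branch:2b-vs-2c", Verdict.INDETERMINATE, 0.0, ("34S/36S",)))
    else:
        # 34S/36S up: the 2b route lost ground, i.e. 2b inhibited relative to 2c
        score = float(np.clip(-branch / (2 * theta), -1.0, 1.0))
        out.append(StepEvidence("branch:2b-vs-2c", _verdict(-branch, theta), score, ("34S/36S",)))
    return out


def inhibited_tags(evidence: list[StepEvidence]) -> set[str]:
    """Tags with an inhibited verdict (branch verdict excluded)."""
    return {
        e.target
        for e in evidence
        if e.verdict is Verdict.INHIBITED and not e.target.startswith("branch:")
    }
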