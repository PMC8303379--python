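"""Model-profile clustering of short expression time courses.

Candidate temporal templates are all integer unit-change profiles over the
ordered timepoints (first entry 0, successive steps bounded by a maximum
unit change), the approach popularized for short time series by the STEM
method. Each gene trajectory — mean log2-CPM deltas relative to the first
timepoint — is assigned to the template it correlates with best; template
over-occupancy is tested by permuting each gene's non-baseline values and
re-assigning, with Bonferroni correction across templates.

Timepoints are treated as ordinal: the 0/1/7-day design is handled as
three equally spaced steps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ImmLncError

logger = logging.getLogger(__name__)

FLAT_PROFILE = -1  # bin for zero-variance trajectories, excluded from testing


@dataclass
class ProfileModel:
    """One candidate temporal template."""

    profile_id: int
    template: tuple[int, ...]
    assigned_genes: list[str] = field(default_factory=list)
    expected_count: float = float("nan")
    p_value: float = float("nan")
    p_corrected: float = float("nan")
    significant: bool = False


def enumerate_profiles(
    n_timepoints: int = 3, max_unit_change: int = 2
) -> list[ProfileModel]:
    """All unit-change templates (0, s1, s1+s2, ...), excluding all-flat.

    Steps range over {-c..c}; ordering is lexicographic in the step
    vector, so profile ids are deterministic.
    """
    if n_timepoints < 2:
        raise ImmLncError("need >= 2 timepoints")
    if max_unit_change < 1:
        raise ImmLncError("max_unit_change must be >= 1")
    c = max_unit_change
    profiles = []
    pid = 0
    for steps in product(range(-c, c + 1), repeat=n_timepoints - 1):
        if all(s == 0 for s in steps):
            continue
        template = tuple(np.concatenate([[0], np.cumsum(steps)]).tolist())
        profiles.append(ProfileModel(profile_id=pid, template=template))
        pid += 1
    return profiles


def _template_matrix(profiles: Sequence[ProfileModel]) -> np.ndarray:
    t = np.array([p.template for p in profiles], dtype=float)
    t -= t.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(t, axis=1)
    return t / norm[:, None]


def _assign_array(traj: np.ndarray, tmpl_z: np.ndarray) -> np.ndarray:
    """Row-wise best-correlated template; FLAT_PROFILE for zero variance.

    Ties go to the lowest profile id (argmax keeps the first maximum).
    """
    centered = traj - traj.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centered, axis=1)
    flat = norm < 1e-12
    safe = np.where(flat, 1.0, norm)
    z = centered / safe[:, None]
    r = z @ tmpl_z.T
    best = np.argmax(r, axis=1)
    best[flat] = FLAT_PROFILE
    return best


def assign_genes(
    trajectories: pd.DataFrame, profiles: Sequence[ProfileModel]
) -> pd.Series:
    """Assign each gene trajectory to its best-correlated template.

    ``trajectories`` is genes x timepoints of log2-CPM deltas relative to
    the first timepoint (first column identically 0). Returns a Series of
    profile ids; zero-variance trajectories get :data:`FLAT_PROFILE`.
    """
    n_tp = len(profiles[0].template)
    if trajectories.shape[1] != n_tp:
        raise ImmLncError(
            f"trajectory length {trajectories.shape[1]} != template length {n_tp}"
        )
    tmpl_z = _template_matrix(profiles)
    best = _assign_array(trajectories.to_numpy(dtype=float), tmpl_z)
    assignment = pd.Series(best, index=trajectories.index, name="profile_id")
    for p in profiles:
        p.assigned_genes = assignment.index[assignment == p.profile_id].tolist()
    return assignment


def profile_significance(
    trajectories: pd.DataFrame,
    profiles: Sequence[ProfileModel],
    n_permutations: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation test of template over-occupancy.

    The null reshuffles each gene's non-baseline timepoint values
    independently and re-assigns; p = (1 + #{permutation count >= observed})
    / (1 + n_permutations), Bonferroni-corrected across templates.
    Zero-variance (flat-binned) genes are excluded.
    """
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} is low; p-value resolution is coarse",
            stacklevel=2,
        )
    tmpl_z = _template_matrix(profiles)
    traj = trajectories.to_numpy(dtype=float)
    observed = _assign_array(traj, tmpl_z)
    active = observed != FLAT_PROFILE
    traj = traj[active]
    observed = observed[active]
    n_profiles = len(profiles)
    obs_counts = np.bincount(observed, minlength=n_profiles)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_profiles, dtype=np.int64)
    perm_total = np.zeros(n_profiles, dtype=np.float64)
    work = traj.copy()
    for _ in range(n_permutations):
        work[:, 1:] = rng.permuted(work[:, 1:], axis=1)
        counts = np.bincount(_assign_array(work, tmpl_z), minlength=n_profiles)
        exceed += counts >= obs_counts
        perm_total += counts
    pvals = (1.0 + exceed) / (1.0 + n_permutations)
    p_corr = np.minimum(pvals * n_profiles, 1.0)
    expected = perm_total / max(n_permutations, 1)

    for p in profiles:
        p.expected_count = float(expected[p.profile_id])
        p.p_value = float(pvals[p.profile_id])
        p.p_corrected = float(p_corr[p.profile_id])
        p.significant = bool(p_corr[p.profile_id] < alpha)
    return pd.DataFrame(
        {
            "profile_id": [p.profile_id for p in profiles],
            "template": [p.template for p in profiles],
            "n_genes": obs_counts,
            "expected_count": expected,
            "p_value": pvals,
            "p_corrected": p_corr,
            "significant": [p.significant for p in profiles],
        }
    )


def cluster_summary(
    assignment: pd.Series,
    trajectories: pd.DataFrame,
    profiles: Sequence[ProfileModel],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean trajectory per occupied profile and a sorted member table.

    Members are ordered by correlation to their template, descending.
    """
    if assignment.empty:
        raise ImmLncError("empty assignment")
    tmpl_z = _template_matrix(profiles)
    traj = trajectories.to_numpy(dtype=float)
    centered = traj - traj.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centered, axis=1)
    z = centered / np.where(norm < 1e-12, 1.0, norm)[:, None]

    summary_rows, member_rows = [], []
    for p in profiles:
        mask = (assignment == p.profile_id).to_numpy()
        if not mask.any():
            continue
        mean_traj = traj[mask].mean(axis=0)
        summary_rows.append(
            {
                "profile_id": p.profile_id,
                "template": p.template,
                "n_genes": int(mask.sum()),
                **{f"t{i}": v for i, v in enumerate(mean_traj)},
            }
        )
        r = z[mask] @ tmpl_z[p.profile_id]
        for g, ri in sorted(
            zip(assignment.index[mask], r), key=lambda t: -t[1]
        ):
            member_rows.append({"profile_id": p.profile_id, "gene_id": g, "r": ri})
    return pd.DataFrame(summary_rows), pd.DataFrame(member_rows)
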