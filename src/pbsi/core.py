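"""The person-based similarity index and its regional diagnostics.

For each subject in a (group, site, modality) cell, the PBSI is the mean of
Spearman rank correlations between that subject's regional profile and the
profiles of every other subject in the same cell — ``n - 1`` coefficients
averaged per subject.  Because the index is rank-based it is invariant to
any per-subject strictly increasing transform, and in particular independent
of global scale (intracranial volume, mean thickness).

Two diagnostics probe whether any single region drives the index:

* leave-one-out — recompute each subject's PBSI with one region removed and
  report the per-region mean absolute change;
* subset resampling — recompute PBSI on random region subsets of increasing
  size and summarize agreement with the full-profile PBSI.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

Cell = tuple[str, str, str]  # (group, site, modality)


@dataclass(frozen=True)
class Profile:
    """One subject's ordered vector of regional measures of one modality."""

    subject_id: str
    modality: str
    values: np.ndarray
    region_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("profile needs a 1-D vector of length >= 2")
        if not np.isfinite(values).all():
            raise ValueError(f"profile {self.subject_id}: non-finite values")
        if self.region_ids is not None and len(self.region_ids) != values.size:
            raise ValueError(f"profile {self.subject_id}: region_ids/value length mismatch")
        object.__setattr__(self, "values", values)


@dataclass
class PBSIResult:
    """Per-subject similarity scores for one (group, site, modality) cell.

    ``scores`` maps subject_id -> PBSI; subjects with a constant profile
    (undefined rank correlation) are excluded from the cell and listed in
    ``excluded`` with a NaN score.
    """

    cell: Cell
    scores: pd.Series
    n_peers: int
    regions_used: tuple[str, ...] | None = None
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        finite = self.scores.dropna()
        if len(finite) and not ((finite >= -1 - 1e-12) & (finite <= 1 + 1e-12)).all():
            raise ValueError("PBSI out of [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        group, site, modality = self.cell
        return pd.DataFrame(
            {
                "subject_id": self.scores.index,
                "group": group,
                "site": site,
                "modality": modality,
                "pbsi": self.scores.to_numpy(),
                "n_peers": self.n_peers,
            }
        )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rho: Pearson correlation of midranks.

    Ties receive average ranks.  Returns NaN (the undefined flag) when
    either vector is constant, i.e. has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need 1-D vectors of length >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    if np.array_equal(rx, ry):  # exact rank agreement
        return 1.0
    if np.array_equal(rx + ry, np.full(rx.size, rx.size + 1.0)):  # exact reversal
        return -1.0
    return float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))


def _rank_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise midranks and a validity mask (False where a row is constant)."""
    ranks = rankdata(values, axis=1)
    valid = ranks.std(axis=1) > 0.0
    return ranks, valid


def pbsi_scores(values: np.ndarray) -> np.ndarray:
    """PBSI for every row of a subjects-by-regions matrix.

    The pairwise Spearman matrix is computed once, on the rank-transformed
    matrix, and reused symmetrically; averaging excludes the diagonal.
    Rows with constant values get NaN and are excluded from everyone's
    average.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D subjects x regions matrix")
    n, p = values.shape
    if n < 2:
        raise ValueError("need >= 2 subjects")
    if p < 2:
        raise ValueError("need >= 2 regions")
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in profile matrix")

    ranks, valid = _rank_matrix(values)
    out = np.full(n, np.nan)
    m = int(valid.sum())
    if m < 2:
        return out
    corr = np.corrcoef(ranks[valid])
    corr = 0.5 * (corr + corr.T)  # exact symmetry
    np.clip(corr, -1.0, 1.0, out=corr)
    # snap float error on exact rank agreement/reversal so degenerate
    # constructions (identical profiles, pure reversals) come out exact
    corr[np.abs(corr - 1.0) < 1e-15] = 1.0
    corr[np.abs(corr + 1.0) < 1e-15] = -1.0
    # summing each row in sorted order makes every PBSI exactly invariant
    # to subject input order; the inf diagonal sorts last and is dropped
    np.fill_diagonal(corr, np.inf)
    ordered = np.sort(corr, axis=1)[:, :-1]
    out[valid] = ordered.sum(axis=1) / (m - 1)
    return np.clip(out, -1.0, 1.0, out=out)


def _profiles_to_matrix(profiles: Sequence[Profile]) -> tuple[np.ndarray, list[str], tuple | None]:
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    first = profiles[0]
    lengths = {p.values.size for p in profiles}
    if len(lengths) != 1:
        raise ValueError(f"mixed profile lengths: {sorted(lengths)}")
    region_sets = {p.region_ids for p in profiles}
    if len(region_sets) != 1:
        raise ValueError("mixed region sets across profiles")
    modalities = {p.modality for p in profiles}
    if len(modalities) != 1:
        raise ValueError(f"mixed modalities: {sorted(modalities)}")
    ids = [p.subject_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated subject ids among profiles")
    return np.vstack([p.values for p in profiles]), ids, first.region_ids


def compute_pbsi(profiles: Sequence[Profile], cell: Cell) -> PBSIResult:
    """Average pairwise Spearman correlation per subject within one cell.

    All profiles must share the same region set; grouping is strictly
    within diagnostic group and within site, which is the caller's contract
    (``cell`` records the stratum).  The result is independent of subject
    input order.
    """
    values, ids, region_ids = _profiles_to_matrix(profiles)
    scores = pbsi_scores(values)
    excluded = tuple(i for i, s in zip(ids, scores) if np.isnan(s))
    if excluded:
        logger.warning(
            "cell %s: excluded %d constant profile(s): %s", cell, len(excluded), excluded
        )
    n_valid = len(ids) - len(excluded)
    if n_valid < 2:
        raise ValueError(f"cell {cell}: fewer than 2 usable profiles")
    return PBSIResult(
        cell=cell,
        scores=pd.Series(scores, index=pd.Index(ids, name="subject_id")),
        n_peers=n_valid - 1,
        regions_used=region_ids,
        excluded=excluded,
    )


def leave_one_out_contributions(
    values: np.ndarray,
    region_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-region mean absolute PBSI change when that region is left out.

    For each region *r*: recompute PBSI with column *r* removed, take each
    subject's ``|PBSI_without_r - PBSI_full|`` and average over subjects.
    Requires >= 3 regions so every reduced profile keeps >= 2.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D subjects x regions matrix")
    n, p = values.shape
    if p < 3:
        raise ValueError(f"leave-one-out needs >= 3 regions, got {p}")
    if region_ids is None:
        region_ids = [f"region{i:03d}" for i in range(p)]
    if len(region_ids) != p:
        raise ValueError("region_ids length mismatch")
    full = pbsi_scores(values)
    deltas = np.empty(p)
    for r in range(p):
        reduced = pbsi_scores(np.delete(values, r, axis=1))
        deltas[r] = np.nanmean(np.abs(reduced - full))
    return pd.DataFrame({"region": list(region_ids), "mean_abs_delta": deltas})


def subset_resampling(
    values: np.ndarray,
    sizes: Sequence[int],
    reps: int,
    seed: int,
    region_ids: Sequence[str] | None = None,
    cell_key: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recompute PBSI on random region subsets of each requested size.

    For each (size, rep) a subset of regions is drawn uniformly without
    replacement from an independent stream keyed by (cell, size, rep), so
    individual runs are reproducible from the master ``seed`` alone.

    Returns
    -------
    runs : DataFrame
        One row per (size, rep, subject): ``size, rep, subject_index, pbsi``
        plus the pipe-joined subset of regions used.
    stability : DataFrame
        One row per size: mean/min Spearman correlation across subjects
        between subset PBSI and full PBSI, and the mean absolute difference.
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sizes = [int(s) for s in sizes]
    for s in sizes:
        if s < 2 or s > p:
            raise ValueError(f"subset size {s} outside [2, {p}]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if region_ids is None:
        region_ids = [f"region{i:03d}" for i in range(p)]
    region_ids = list(region_ids)

    full = pbsi_scores(values)
    cell_tag = zlib.crc32(cell_key.encode())
    run_rows = []
    stab_rows = []
    for size in sizes:
        corrs = np.empty(reps)
        mads = np.empty(reps)
        for rep in range(reps):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(cell_tag, size, rep))
            )
            subset = np.sort(rng.choice(p, size=size, replace=False))
            sub_scores = pbsi_scores(values[:, subset])
            regions = "|".join(region_ids[i] for i in subset)
            for i in range(n):
                run_rows.append(
                    {"size": size, "rep": rep, "subject_index": i,
                     "pbsi": sub_scores[i], "regions": regions}
                )
            mask = np.isfinite(sub_scores) & np.isfinite(full)
            corrs[rep] = spearman_rho(sub_scores[mask], full[mask]) if mask.sum() > 2 else np.nan
            mads[rep] = float(np.nanmean(np.abs(sub_scores - full)))
        finite = corrs[np.isfinite(corrs)]  # rho undefined when scores are constant
        stab_rows.append(
            {
                "size": size,
                "n_reps": reps,
                "mean_spearman_with_full": float(finite.mean()) if finite.size else float("nan"),
                "min_spearman_with_full": float(finite.min()) if finite.size else float("nan"),
                "mean_abs_diff": float(np.mean(mads)),
            }
        )
    return pd.DataFrame(run_rows), pd.DataFrame(stab_rows)
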