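"""CompPASS semi-quantitative statistics and bait-prey feature vectors.

For the stats matrix ``X`` with ``X[i, j]`` the mean PSM of prey *j* across
the technical replicates of bait *i* (zero where undetected, over all *k*
baits of the study):

- ``z[i, j] = (X[i, j] - mu_j) / sigma_j`` with ``mu_j``/``sigma_j`` the mean
  and (sample) SD of prey *j* across all baits; a constant prey (``sigma = 0``)
  gets ``z = 0`` rather than NaN so it cannot poison the classifier.
- ``wd[i, j] = sqrt( X[i, j] * ((k / f_j) * omega_j) ** p[i, j] )`` with
  ``f_j`` the number of baits detecting prey *j*, ``omega_j = max(1,
  sigma_j / mu_j)`` and ``p[i, j]`` the number of replicates of bait *i* in
  which the prey was seen: rare, reproducible, abundant preys score high.
- ``entropy[i, j]`` is the Shannon entropy (bits) of the pseudocounted
  replicate counts ``q_r = (c_r + 1/R) / sum_s (c_s + 1/R)``; even counts
  across R replicates give the maximum ``log2 R``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from altppi.counts import SpectralCountMatrix

FEATURE_COLUMNS = [
    "z",
    "wd",
    "entropy",
    "reproducibility",  # p_rep / R
    "prey_frequency",  # f / k
    "log_avg_psm",  # log1p(x_avg)
    "bait_ratio",  # prey PSMs over the bait's own PSMs in the same runs
    "plate_frequency",  # fraction of same-plate baits detecting the prey
    "unique_peptides",  # mean unique-peptide tally across replicates
]


def replicate_entropy(counts: np.ndarray, n_replicates: int) -> float:
    """Pseudocounted Shannon entropy (bits) of per-replicate PSM counts."""
    c = np.zeros(n_replicates, dtype=float)
    c[: len(counts)] = counts
    q = (c + 1.0 / n_replicates)
    q = q / q.sum()
    return float(-(q * np.log2(q)).sum())


def compute_stats(matrix: SpectralCountMatrix) -> pd.DataFrame:
    """CompPASS statistics for every (bait, detected prey) pair.

    Returns a frame with columns bait_id, prey, prey_kind, x_avg, z, wd,
    entropy, f, p_rep, k. Requires at least two baits (Z undefined otherwise).
    """
    entries = matrix.entries
    if entries.empty:
        raise ValueError("empty spectral count matrix")
    baits = matrix.baits()
    k = len(baits)
    if k < 2:
        raise ValueError("Z-scores require at least two baits")
    reps = matrix.design.groupby("bait_id")["replicate_index"].nunique().to_dict()

    # mean PSM per (bait, prey) over that bait's replicates (absent replicates = 0)
    sums = entries.groupby(["bait_id", "entity"], sort=True)["psm_count"].sum()
    x = sums.reset_index()
    x["x_avg"] = [s / reps[b] for b, s in zip(x["bait_id"], x["psm_count"])]
    pivot = x.pivot(index="bait_id", columns="entity", values="x_avg").reindex(baits).fillna(0.0)

    mu = pivot.mean(axis=0)
    sigma = pivot.std(axis=0, ddof=1)
    f = (pivot > 0).sum(axis=0)
    omega = np.maximum(1.0, np.where(mu > 0, sigma / mu.replace(0, np.nan), 1.0))
    omega = pd.Series(omega, index=mu.index).fillna(1.0)

    p_rep = entries.groupby(["bait_id", "entity"])["replicate_index"].nunique()
    uniq = entries.groupby(["bait_id", "entity"])["unique_peptides"].sum()
    kinds = entries.drop_duplicates("entity").set_index("entity")["entity_kind"]

    rep_counts = entries.set_index(["bait_id", "entity", "replicate_index"])["psm_count"].sort_index()
    rows = []
    for (bait, prey), x_avg in sums.items():
        R = reps[bait]
        x_avg = x_avg / R
        s = float(sigma[prey])
        z = 0.0 if s == 0 else (x_avg - float(mu[prey])) / s
        p = int(p_rep[(bait, prey)])
        wd = float(np.sqrt(x_avg * ((k / float(f[prey])) * float(omega[prey])) ** p))
        c = rep_counts.loc[bait, prey].to_numpy()
        rows.append(
            {
                "bait_id": bait,
                "prey": prey,
                "prey_kind": kinds[prey],
                "x_avg": x_avg,
                "z": z,
                "wd": wd,
                "entropy": replicate_entropy(c, R),
                "f": int(f[prey]),
                "p_rep": p,
                "k": k,
                "unique_peptides_total": float(uniq[(bait, prey)]),
            }
        )
    return pd.DataFrame(rows)


def build_features(
    stats: pd.DataFrame, matrix: SpectralCountMatrix, design: pd.DataFrame
) -> pd.DataFrame:
    """Nine-feature vectors for all candidate (bait, prey) pairs.

    Candidates are all (bait, detected prey) pairs except the bait's own gene.
    Columns: bait_id, prey, prey_kind, plate_id, then :data:`FEATURE_COLUMNS`.
    """
    reps = design.groupby("bait_id")["replicate_index"].nunique().to_dict()
    plates = design.drop_duplicates("bait_id").set_index("bait_id")["plate_id"].to_dict()
    plate_sizes = pd.Series(plates).value_counts().to_dict()

    # bait's own total PSMs per bait experiment
    own = (
        matrix.entries[matrix.entries["entity"] == matrix.entries["bait_id"]]
        .groupby("bait_id")["psm_count"]
        .sum()
        .to_dict()
    )
    # plate-level prey detection frequency
    det = stats[["bait_id", "prey"]].copy()
    det["plate_id"] = det["bait_id"].map(plates)
    plate_freq = det.drop_duplicates().groupby(["plate_id", "prey"]).size().to_dict()

    out = stats[stats["bait_id"] != stats["prey"]].copy()
    out["plate_id"] = out["bait_id"].map(plates)
    out["reproducibility"] = out["p_rep"] / out["bait_id"].map(reps)
    out["prey_frequency"] = out["f"] / out["k"]
    out["log_avg_psm"] = np.log1p(out["x_avg"])
    out["bait_ratio"] = [
        (x_avg * reps[b]) / own[b] if own.get(b, 0) > 0 else 0.0
        for b, x_avg in zip(out["bait_id"], out["x_avg"])
    ]
    out["plate_frequency"] = [
        plate_freq.get((p, prey), 0) / plate_sizes[p]
        for p, prey in zip(out["plate_id"], out["prey"])
    ]
    out["unique_peptides"] = out["unique_peptides_total"] / out["bait_id"].map(reps)

    cols = ["bait_id", "prey", "prey_kind", "plate_id"] + FEATURE_COLUMNS
    feats = out[cols].reset_index(drop=True)
    bad = ~np.isfinite(feats[FEATURE_COLUMNS].to_numpy()).all(axis=1)
    if bad.any():
        import warnings

        warnings.warn(f"imputing {int(bad.sum())} non-finite feature values as 0")
        feats.loc[:, FEATURE_COLUMNS] = feats[FEATURE_COLUMNS].replace([np.inf, -np.inf], np.nan).fillna(0.0)
    return feats
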