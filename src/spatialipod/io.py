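"""File I/O: CSV datasets, dense/GAL/GWT weight files, run configuration.

Weight-file dialects follow the GeoDa conventions:

* GAL (contiguity): a header line whose last-but-one token is the number of
  units, then per-unit records ``<id> <n_neighbors>`` followed by a line of
  neighbor ids; binary weights, expected symmetric.
* GWT (distances): the same header, then one ``<i> <j> <distance>`` triple
  per line; converted to inverse-distance weights.  Triples are directed —
  the reverse entry exists only if listed.

IDs are 1-based by default (the common GeoDa export) and are mapped onto
the row order of the dataset; the mapping is returned for auditing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .ipod import RegressionProblem
from .sem import SpatialWeights, row_standardize

__all__ = [
    "RunConfig",
    "read_dataset",
    "read_weights",
    "write_detection_report",
]


@dataclass
class RunConfig:
    """Plain-text (JSON) run configuration for the command-line surface."""

    rule: str = "soft"
    psi_kind: str = "cauchy"
    mu: Optional[float] = None
    n_lambda: int = 100
    tol: float = 1e-8
    max_iter: int = 500
    report_scale: str = "transformed"
    seed: int = 0
    log_level: str = "info"
    standardize_weights: bool = True

    def __post_init__(self):
        if self.rule not in ("soft", "hard"):
            raise ValueError(f"rule must be 'soft' or 'hard', got {self.rule!r}")
        if self.report_scale not in ("transformed", "original"):
            raise ValueError(f"bad report_scale {self.report_scale!r}")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be at least 2")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be positive and max_iter at least 1")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _read_numeric_csv(path, name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, header=None)
    except Exception as exc:
        raise ValueError(f"could not parse {name} file {path}: {exc}") from exc
    # a non-numeric first row is taken as a header
    if df.apply(lambda c: pd.to_numeric(c, errors="coerce")).iloc[0].isna().all():
        df = pd.read_csv(path)
    return df.apply(lambda c: pd.to_numeric(c, errors="coerce"))


def read_dataset(x_path, y_path, drop_missing: bool = False):
    """Read a design matrix and response from CSV.

    Rows with missing or non-numeric cells are rejected with their indices
    listed; with ``drop_missing=True`` they are dropped instead (the
    analysis then runs on the remaining rows) and the dropped indices are
    returned.

    Returns ``(problem, dropped_rows)``.
    """
    Xdf = _read_numeric_csv(x_path, "design")
    ydf = _read_numeric_csv(y_path, "response")
    if ydf.shape[1] != 1:
        raise ValueError(f"response file must have one column, got {ydf.shape[1]}")
    if Xdf.shape[0] != ydf.shape[0]:
        raise ValueError(
            f"row-count mismatch: design has {Xdf.shape[0]} rows, "
            f"response has {ydf.shape[0]}"
        )
    bad = Xdf.isna().any(axis=1) | ydf.isna().any(axis=1)
    dropped = np.flatnonzero(bad.to_numpy())
    if dropped.size and not drop_missing:
        raise ValueError(
            f"missing or non-numeric values in rows {dropped.tolist()}; "
            "pass drop_missing=True to exclude them"
        )
    keep = ~bad.to_numpy()
    prob = RegressionProblem(Xdf.to_numpy()[keep], ydf.to_numpy().ravel()[keep])
    return prob, dropped


def _read_gal(path, ids: Optional[list]) -> Tuple[np.ndarray, Dict]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split()
    # GeoDa header: "0 n shapefile idvar" or just "n"
    n = int(header[1]) if len(header) >= 2 else int(header[0])
    records = {}
    i = 1
    while i < len(lines):
        unit, deg = lines[i].split()[:2]
        deg = int(deg)
        neigh = lines[i + 1].split() if deg > 0 else []
        if len(neigh) != deg:
            raise ValueError(
                f"GAL record for unit {unit} promises {deg} neighbors, "
                f"lists {len(neigh)}"
            )
        records[unit] = neigh
        i += 2
    if ids is None:
        ids = [str(k + 1) for k in range(n)]  # 1-based GeoDa convention
    index = {u: k for k, u in enumerate(ids)}
    unknown = sorted(set(records) - set(index)) + sorted(
        {v for vs in records.values() for v in vs} - set(index)
    )
    if unknown:
        raise ValueError(f"GAL file references unknown unit ids: {unknown}")
    W = np.zeros((n, n))
    for u, vs in records.items():
        for v in vs:
            W[index[u], index[v]] = 1.0
    if not np.allclose(W, W.T):
        bad = np.argwhere(~np.isclose(W, W.T))[:4].tolist()
        raise ValueError(f"asymmetric GAL adjacency near entries {bad}")
    return W, index


def _read_gwt(path, ids: Optional[list]) -> Tuple[np.ndarray, Dict]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split()
    n = int(header[1]) if len(header) >= 2 else int(header[0])
    if ids is None:
        ids = [str(k + 1) for k in range(n)]
    index = {u: k for k, u in enumerate(ids)}
    W = np.zeros((n, n))
    for ln in lines[1:]:
        u, v, d = ln.split()[:3]
        if u not in index or v not in index:
            raise ValueError(f"GWT file references unknown unit ids: {u!r}, {v!r}")
        d = float(d)
        if d <= 0:
            raise ValueError(f"nonpositive distance {d} between {u} and {v}")
        W[index[u], index[v]] = 1.0 / d  # inverse-distance weight
    return W, index


def read_weights(
    path,
    fmt: str = "csv",
    standardize: bool = True,
    ids: Optional[list] = None,
):
    """Read a spatial weight matrix (dense CSV, GAL or GWT).

    Returns ``(weights, id_map)`` where ``id_map`` maps file unit ids to row
    indices (identity for CSV).
    """
    if fmt == "csv":
        W = pd.read_csv(path, header=None).to_numpy(dtype=float)
        id_map = {str(k + 1): k for k in range(W.shape[0])}
    elif fmt == "gal":
        W, id_map = _read_gal(path, ids)
    elif fmt == "gwt":
        W, id_map = _read_gwt(path, ids)
    else:
        raise ValueError(f"unknown weights format {fmt!r} (expected csv, gal or gwt)")
    w = SpatialWeights(W=W, source=str(path))
    if standardize:
        w = row_standardize(w)
        w.source = str(path)
    return w, id_map


def write_detection_report(fit, out_dir, dropped_rows=None) -> Dict[str, Path]:
    """Write the per-observation table and model summary for a spatial fit.

    Numeric output keeps full repr precision so write-then-read round-trips
    exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = len(fit.gamma_tilde)
    flagged = np.zeros(n, dtype=int)
    flagged[fit.outlier_idx] = 1
    obs = pd.DataFrame(
        {
            "gamma_tilde": fit.gamma_tilde,
            "gamma_original_scale": fit.gamma_back,
            "flagged": flagged,
        }
    )
    obs_path = out_dir / "observations.csv"
    obs.to_csv(obs_path, index_label="row", float_format="%.17g")

    summary = {
        "mu_hat": fit.sem.mu_hat,
        "mu_method": fit.sem.method,
        "psi_kind": fit.sem.psi_kind,
        "sem_converged": bool(fit.sem.converged),
        "sigma_hat": fit.sem.sigma_hat,
        "beta_hat": np.asarray(fit.beta_hat).tolist(),
        "rule": fit.ipod.rule,
        "lambda_selected": fit.ipod.lam,
        "bic_star": fit.ipod.bic_star,
        "n_outliers": int(fit.outlier_idx.size),
        "outlier_rows": fit.outlier_idx.tolist(),
        "report_scale": fit.report_scale,
        "dropped_rows": list(map(int, dropped_rows)) if dropped_rows is not None else [],
    }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2) + "\n")

    path = pd.DataFrame(
        {
            "lambda": fit.ipod.lambda_grid,
            "bic_star": fit.ipod.bic_path,
            "n_flagged": fit.ipod.df_path,
        }
    )
    path_path = out_dir / "bic_path.csv"
    path.to_csv(path_path, index=False, float_format="%.17g")
    return {"observations": obs_path, "summary": summary_path, "bic_path": path_path}
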