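"""Expression-matrix I/O, preprocessing, and network construction.

A cell-type-averaged expression matrix (genes as rows, cell types as
columns, nonnegative counts) parameterizes the identity network directly:
after a log1p transform and a mean/std variability filter the cell-type
profiles become the unit-normalised rows of the binding/coupling matrix,
and the terminal inverse temperature is calibrated as the smallest beta at
which every cell type is a stable attractor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attractors import AttractorSet, pattern_stability_report
from .dynamics import Trajectory
from .network import RegulatoryNetwork

__all__ = [
    "ExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "preprocess_expression",
    "network_from_profiles",
    "calibrate_beta",
    "write_trajectory",
    "read_trajectory",
    "write_attractors",
]

LOG4 = float(np.log(4.0))


@dataclass
class ExpressionMatrix:
    """Genes x cell types, nonnegative; thin validated pandas wrapper."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicated gene name: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicated cell-type name: {dup!r}")
        if df.isna().any().any():
            raise ValueError("missing values in expression matrix")
        if (df.values < 0).any():
            raise ValueError("negative expression values")
        self.data = df.astype(float)

    @property
    def genes(self):
        return list(self.data.index)

    @property
    def cell_types(self):
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.values


def read_expression_matrix(path, dialect: str | None = None
                           ) -> ExpressionMatrix:
    """Read a CSV/TSV with a header row of cell types and first column of
    gene names.  ``dialect``: "csv", "tsv" or None (sniffed)."""
    sep = {"csv": ",", "tsv": "\t", None: None}[dialect]
    df = pd.read_csv(path, sep=sep, index_col=0,
                     engine="python" if sep is None else "c")
    return ExpressionMatrix(data=df)


def write_expression_matrix(mat: ExpressionMatrix, path,
                            dialect: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    mat.data.to_csv(path, sep=sep)


def preprocess_expression(mat: ExpressionMatrix,
                          mean_threshold: float = LOG4,
                          std_threshold: float = LOG4,
                          ddof: int = 0) -> ExpressionMatrix:
    """log1p-transform, then keep genes whose mean AND std (population std
    by default) across cell types strictly exceed the thresholds.

    The log transform reduces the variance of the resulting network rows
    and hence the sensitivity to TF choice; the filter keeps the TFs that
    vary between identities."""
    if mean_threshold < 0 or std_threshold < 0:
        raise ValueError("thresholds must be >= 0")
    df = np.log1p(mat.data)
    means = df.mean(axis=1)
    stds = df.std(axis=1, ddof=ddof)
    keep = (means > mean_threshold) & (stds > std_threshold)
    if not keep.any():
        raise ValueError("no genes survive filtering")
    return ExpressionMatrix(data=df.loc[keep])


def network_from_profiles(mat: ExpressionMatrix, beta: float | None = None,
                          weights=None, beta_grid=None) -> RegulatoryNetwork:
    """Identity network parameterized by observed cell-type profiles.

    Cell types become enhancer-type rows (Xi = Q), unit-normalised; w = 0
    unless given; beta calibrated (smallest value stabilising every
    pattern) when omitted."""
    X = mat.values.T  # cell types x genes
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        bad = mat.cell_types[int(np.argmax(norms == 0))]
        raise ValueError(f"zero-norm profile for cell type {bad!r}")
    rows = X / norms[:, None]
    # near-duplicate profiles collapse to one attractor; warn early
    G = rows @ rows.T
    np.fill_diagonal(G, 0.0)
    if G.max(initial=0.0) > 1.0 - 1e-12:
        import warnings
        i, j = np.unravel_index(np.argmax(G), G.shape)
        warnings.warn(
            f"cell types {mat.cell_types[i]!r} and {mat.cell_types[j]!r} "
            "have identical profiles; consider merging them "
            "(reduce_to_types)", stacklevel=2)
    w = np.zeros(rows.shape[0]) if weights is None else np.asarray(weights)
    net = RegulatoryNetwork(
        tf_names=tuple(mat.genes),
        enhancer_names=tuple(mat.cell_types),
        binding=rows, coupling=rows, weights=w, beta=1.0)
    if beta is None:
        beta = calibrate_beta(net, beta_grid)
    return net.with_beta(beta)


def calibrate_beta(net: RegulatoryNetwork, beta_grid=None) -> float:
    """Smallest grid beta at which every pattern is a stable fixed point."""
    if beta_grid is None:
        beta_grid = np.geomspace(0.5, 512.0, 31)
    for b in np.sort(np.asarray(beta_grid, dtype=float)):
        reports = pattern_stability_report(net, beta=b)
        if all(r.is_stable for r in reports):
            return float(b)
    raise ValueError("no beta on the grid stabilises all patterns")


# ---------------------------------------------------------------------------
# tabular writers


def write_trajectory(traj: Trajectory, net: RegulatoryNetwork, path) -> None:
    """CSV with stable column order: t, beta, x:<tf>..., p:<enhancer>...."""
    cols = {"t": traj.times, "beta": traj.beta_values}
    for j, name in enumerate(net.tf_names):
        cols[f"x:{name}"] = traj.states[:, j]
    for i, name in enumerate(net.enhancer_names):
        cols[f"p:{name}"] = traj.activities[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    xcols = [c for c in df.columns if c.startswith("x:")]
    pcols = [c for c in df.columns if c.startswith("p:")]
    return Trajectory(times=df["t"].values, beta_values=df["beta"].values,
                      states=df[xcols].values, activities=df[pcols].values)


def write_attractors(aset: AttractorSet, net: RegulatoryNetwork, path
                     ) -> None:
    rows = []
    for fp in aset:
        row = {"label": fp.label, "stability": fp.stability,
               "residual": fp.residual,
               "leading_eigenvalue": fp.leading_eigenvalue_real_part}
        row.update({f"x:{n}": v for n, v in zip(net.tf_names, fp.x)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_manifest(path, **entries) -> None:
    """Run-provenance JSON (inputs, parameters, seeds, package version)."""
    from . import __version__
    payload = {"package": "enhancernet", "version": __version__}
    payload.update(entries)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)
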