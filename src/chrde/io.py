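"""Delimited-text readers and writers for expression matrices, survival
metadata and fit results.

Tab-separated is canonical; comma-separated files are accepted. Expression
matrices carry a header row and an index column; an orientation flag says
whether genes are on rows or columns. Result files start with a metadata
comment line recording the package version and seed so runs can be audited.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import SurvivalDataset
from .evolve import concordance_index


class UserInputError(ValueError):
    """Malformed or inconsistent user-supplied input."""


def _header_duplicates(path: Path, sep: str) -> list[str]:
    """Duplicate names in the raw header line (pandas silently renames them)."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            names = line.rstrip("\n").split(sep)[1:]
            return sorted({n for n in names if names.count(n) > 1})
    return []


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except Exception as exc:
        raise UserInputError(f"could not parse {path}: {exc}") from exc
    dup = _header_duplicates(path, sep)
    if dup:
        raise UserInputError(f"duplicate column names in {path}: {dup}")
    return df


def load_expression(path, orientation: str = "columns") -> pd.DataFrame:
    """Load an expression matrix as samples x features.

    ``orientation`` declares the on-disk layout of genes: "rows" (one row per
    gene, samples in columns) or "columns".
    """
    if orientation not in ("rows", "columns"):
        raise UserInputError("orientation must be 'rows' or 'columns'")
    df = _read_table(path)
    if orientation == "rows":
        df = df.T
    dup = df.columns[df.columns.duplicated()].unique().tolist()
    if dup:
        raise UserInputError(f"duplicate feature names in {path}: {dup}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise UserInputError(f"non-numeric values in columns: {non_numeric}")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise UserInputError(f"missing values in columns: {bad}")
    return df


def load_survival(path) -> pd.DataFrame:
    """Load survival metadata: index = sample id, columns time and event."""
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    if "time" not in cols or "event" not in cols:
        raise UserInputError(
            f"survival table {path} must have 'time' and 'event' columns, "
            f"found {list(df.columns)}"
        )
    out = df[[cols["time"], cols["event"]]].copy()
    out.columns = ["time", "event"]
    return out


def load_dataset(expression_path, survival_path, orientation="columns") -> SurvivalDataset:
    """Join expression and survival tables on sample id."""
    expr = load_expression(expression_path, orientation)
    surv = load_survival(survival_path)
    missing = [s for s in expr.index if s not in surv.index]
    if missing:
        raise UserInputError(f"samples without survival metadata: {missing[:5]}")
    surv = surv.loc[expr.index]
    return SurvivalDataset(
        expr.to_numpy(dtype=float),
        surv["time"].to_numpy(dtype=float),
        surv["event"].to_numpy(dtype=float),
        feature_names=list(expr.columns),
        sample_ids=[str(s) for s in expr.index],
    )


def _meta_line(seed) -> str:
    return f"# chrde {__version__} seed={seed}"


def config_hash(config: dict) -> str:
    blob = repr(sorted(config.items())).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_imputed(imputed, path, seed=None) -> None:
    """Audit dump of the imputed dataset (intercept column included)."""
    df = pd.DataFrame(imputed.X[:, 1:], columns=imputed.feature_names or None)
    df.insert(0, "y_imputed", imputed.y)
    with open(path, "w") as fh:
        fh.write(_meta_line(seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_results(results, metrics: dict | None, out_prefix, seed=None) -> list[str]:
    """Write selection, hyperparameters/history and metrics files.

    Produces ``<prefix>.coefficients.tsv`` (selected features with
    coefficients), ``<prefix>.fit.tsv`` (hyperparameters plus any DE fitness
    history) and, when ``metrics`` is given, ``<prefix>.metrics.tsv`` with
    exactly the columns mse, ci, n_selected.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []

    coef_path = f"{prefix}.coefficients.tsv"
    coefs = results.coefficients
    sel = coefs.iloc[results.selected]
    with open(coef_path, "w") as fh:
        fh.write(_meta_line(seed) + "\n")
        fh.write("feature\tbeta\n")
        fh.write(f"(intercept)\t{results.intercept:.10g}\n")
        for name, val in sel.items():
            fh.write(f"{name}\t{val:.10g}\n")
    written.append(coef_path)

    fit_path = f"{prefix}.fit.tsv"
    with open(fit_path, "w") as fh:
        fh.write(_meta_line(seed) + "\n")
        fh.write("key\tvalue\n")
        fh.write(f"penalty\t{results.penalty}\n")
        if results.hyperparams is not None:
            p = results.hyperparams
            fh.write(f"a\t{p.a:.10g}\nb\t{p.b:.10g}\ngamma\t{p.gamma:.10g}\n")
        if results.history is not None:
            fh.write("generation\tbest_fitness\n")
            for gen, fit, _ in results.history:
                fh.write(f"{gen}\t{fit:.10g}\n")
    written.append(fit_path)

    if metrics is not None:
        metrics_path = f"{prefix}.metrics.tsv"
        with open(metrics_path, "w") as fh:
            fh.write(_meta_line(seed) + "\n")
            fh.write("mse\tci\tn_selected\n")
            fh.write(
                f"{metrics['mse']:.10g}\t{metrics['ci']:.10g}\t{metrics['n_selected']}\n"
            )
        written.append(metrics_path)
    return written


def read_coefficients(path) -> tuple[float, pd.Series]:
    """Read a coefficients TSV back into (intercept, named coefficient series)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != ["feature", "beta"]:
        raise UserInputError(f"{path} is not a coefficients file")
    inter = df[df["feature"] == "(intercept)"]["beta"]
    intercept = float(inter.iloc[0]) if len(inter) else 0.0
    coef = df[df["feature"] != "(intercept)"].set_index("feature")["beta"]
    return intercept, coef


def evaluate_files(
    coef_path, expression_path, survival_path,
    orientation="columns", metric_scale: str = "log", clip: float = 500.0,
) -> dict:
    """Recompute MSE and concordance of a written model on held-out data."""
    intercept, coef = read_coefficients(coef_path)
    data = load_dataset(expression_path, survival_path, orientation)
    missing = [f for f in coef.index if f not in data.feature_names]
    if missing:
        raise UserInputError(f"model features absent from data: {missing[:5]}")
    cols = [data.feature_names.index(f) for f in coef.index]
    lin = intercept + data.X[:, cols] @ coef.to_numpy()
    if metric_scale == "log":
        mse = float(np.mean((np.log(data.tau) - lin) ** 2))
    else:
        mse = float(np.mean((data.tau - np.exp(np.clip(lin, -clip, clip))) ** 2))
    ci = concordance_index(data.tau, data.delta, lin)
    return {"mse": mse, "ci": ci, "n_selected": int(len(coef))}
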