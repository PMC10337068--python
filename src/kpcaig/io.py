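"""Readers/writers, model persistence and the end-to-end pipeline.

Matrices are plain delimited text (TSV/CSV) with a header row and a
leading identifier column. GEO series matrices are conventionally
features-by-samples (probes as rows); pass
``orientation="features-by-samples"`` to transpose on load. Models are
persisted as a single ``.npz`` archive holding every array plus a JSON
metadata block, versioned so stale archives fail loudly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kernels import KernelSpec
from .kpca import KPCAModel, fit, select_sigma
from .ranking import rank_features, write_ranking

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "save_model",
    "load_model",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

_ORIENTATIONS = ("samples-by-features", "features-by-samples")
_MISSING_POLICIES = ("error", "drop-feature", "mean-impute")


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(
    path,
    orientation: str = "samples-by-features",
    delimiter: str | None = None,
    missing_policy: str = "error",
) -> pd.DataFrame:
    """Load a delimited numeric matrix as a samples-by-features DataFrame.

    The first column holds row identifiers, the header row column
    identifiers. ``missing_policy`` is one of ``error`` (default),
    ``drop-feature`` (drop any feature column containing NA, with a
    warning) or ``mean-impute`` (replace NA by the feature mean).
    """
    path = Path(path)
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    if missing_policy not in _MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {_MISSING_POLICIES}")
    sep = _delimiter_for(path, delimiter)
    if orientation == "samples-by-features":
        # pandas mangles duplicate header names; check the raw header
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        dups = pd.Index(header)[pd.Index(header).duplicated()].unique().tolist()
        if dups:
            raise ValueError(f"duplicate feature ids in {path.name}: {dups[:10]}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "features-by-samples":
        df = df.T
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        where = f"feature {col!r}" + (f", sample {bad.index[0]!r}" if len(bad) else "")
        raise ValueError(f"non-numeric cell in {path.name} at {where}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in {path.name}: {dups[:10]}")
    if df.isna().any().any():
        na_cols = df.columns[df.isna().any()].tolist()
        if missing_policy == "error":
            raise ValueError(
                f"missing values in feature(s) {na_cols[:10]} of {path.name}; "
                "choose a missing_policy to proceed"
            )
        if missing_policy == "drop-feature":
            logger.warning("dropping %d feature(s) with missing values: %s",
                           len(na_cols), na_cols[:10])
            df = df.drop(columns=na_cols)
        else:
            logger.warning("mean-imputing missing values in %d feature(s)", len(na_cols))
            df = df.fillna(df.mean())
    if df.shape[0] < 2:
        raise ValueError(f"need at least 2 samples, got {df.shape[0]}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    logger.info("loaded %s: n=%d samples, p=%d features", path.name, *df.shape)
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path, delimiter: str | None = None) -> None:
    path = Path(path)
    df.to_csv(path, sep=_delimiter_for(path, delimiter))


def read_labels(path, delimiter: str | None = None) -> pd.Series:
    """Two-column (sample_id, label) table as a Series indexed by sample."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), index_col=0)
    return df.iloc[:, 0]


def save_model(model: KPCAModel, path) -> None:
    """Persist a fitted model as a single .npz archive."""
    path = Path(path)
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "package_version": __version__,
        "kernel_family": model.kernel.family,
        "kernel_sigma": model.kernel.sigma,
        "q": model.q,
        "scaled": model.scaled,
        "feature_ids": model.feature_ids,
        "sample_ids": model.sample_ids,
    }
    np.savez_compressed(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        eigenvalues=model.eigenvalues,
        dual_coefs=model.dual_coefs,
        spectrum=model.spectrum,
        X=model.X,
        K=model.K,
        K_col_means=model.K_col_means,
        K_grand_mean=np.array(model.K_grand_mean),
        feature_means=model.feature_means,
        feature_scales=model.feature_scales,
    )


def load_model(path) -> KPCAModel:
    path = Path(path)
    try:
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["meta"].tobytes()).decode())
            arrays = {k: archive[k] for k in archive.files if k != "meta"}
    except Exception as exc:  # corrupted or foreign file
        raise ValueError(f"cannot read model archive {path}: {exc}") from exc
    version = meta.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model archive format version {version} != supported {MODEL_FORMAT_VERSION}"
        )
    sigma = meta["kernel_sigma"]
    return KPCAModel(
        kernel=KernelSpec(meta["kernel_family"],
                          None if sigma is None else float(sigma)),
        q=int(meta["q"]),
        eigenvalues=arrays["eigenvalues"],
        dual_coefs=arrays["dual_coefs"],
        spectrum=arrays["spectrum"],
        X=arrays["X"],
        feature_ids=list(meta["feature_ids"]),
        sample_ids=list(meta["sample_ids"]),
        K=arrays["K"],
        K_col_means=arrays["K_col_means"],
        K_grand_mean=float(arrays["K_grand_mean"]),
        feature_means=arrays["feature_means"],
        feature_scales=arrays["feature_scales"],
        scaled=bool(meta["scaled"]),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, outdir) -> dict:
    """Run fit -> rank (-> plots) from a config dict and write a manifest.

    Recognized keys: ``input`` (matrix path) or ``data`` (DataFrame),
    ``orientation``, ``kernel`` (default rbf), ``sigma`` or
    ``sigma_grid``, ``q`` (required), ``scale`` (default True),
    ``scale_scores`` (display multiplier for the ranking TSV), ``top``,
    ``plots`` (list of feature names to draw arrow fields for), and
    ``seed``. Artifacts (model archive, ranking TSV, figures) plus a
    ``manifest.json`` recording parameters, versions and output
    checksums are written under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "load"
    try:
        if "data" in config:
            X = config["data"]
        else:
            X = read_matrix(
                config["input"],
                orientation=config.get("orientation", "samples-by-features"),
                missing_policy=config.get("missing_policy", "error"),
            )
        q = int(config["q"])
        family = config.get("kernel", "rbf")
        sigma_table = None
        stage = "sigma-selection"
        if family == "rbf":
            if config.get("sigma") is not None:
                sigma = float(config["sigma"])
            else:
                sigma, sigma_table = select_sigma(
                    X, grid=config.get("sigma_grid"), q=q,
                    scale=config.get("scale", True), return_table=True,
                )
            spec = KernelSpec("rbf", sigma)
        else:
            spec = KernelSpec("linear")
        stage = "fit"
        model = fit(X, spec, q=q, scale=config.get("scale", True))
        model_path = outdir / "model.npz"
        save_model(model, model_path)
        stage = "rank"
        ranking = rank_features(model)
        ranking_path = outdir / "ranking.tsv"
        write_ranking(ranking, ranking_path,
                      scale=config.get("scale_scores", 1.0),
                      top=config.get("top"))
        figures = []
        stage = "plot"
        if config.get("plots"):
            from . import viz

            fig_path = outdir / "samples.svg"
            viz.sample_plot(model, path=fig_path)
            figures.append(fig_path)
            for name in config["plots"]:
                if name is True:
                    continue
                j = model.feature_ids.index(str(name))
                fpath = outdir / f"arrows_{name}.svg"
                viz.variable_arrow_field(model, j, path=fpath)
                figures.append(fpath)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    artifacts = [model_path, ranking_path, *figures]
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in config.items()
            if k != "data"
        },
        "kernel": {"family": spec.family, "sigma": spec.sigma},
        "q": model.q,
        "n": model.n,
        "p": model.p,
        "seed": config.get("seed"),
        "sigma_table": (sigma_table.to_dict(orient="list")
                        if sigma_table is not None else None),
        "elapsed_seconds": round(time.time() - t0, 3),
        "outputs": {p.name: _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline finished in %.1fs; artifacts in %s",
                manifest["elapsed_seconds"], outdir)
    return manifest
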