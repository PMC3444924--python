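"""Readers/writers for expression tables and result files.

Expression data travel as tab-separated text, one file per replicate: a
``time`` column followed by one column per gene, optional ``#``-prefixed
header comments.  Round trips are lossless at full float precision.
Identified networks are written both as JSON (full parameterisation and run
trace) and as a tab-separated edge list importable as SIF-style network
text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .identify import IdentifiedNetwork
from .robustness import NetworkEnsemble, RobustNetwork
from .ssystem import ExpressionDataset


def write_expression_tables(
    data: ExpressionDataset, out_dir, *, prefix: str = "replicate", header: dict | None = None
) -> list[Path]:
    """Write one TSV per replicate; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    head = "".join(f"# {k}: {v}\n" for k, v in (header or {}).items())
    for k in range(data.n_replicates):
        path = out_dir / f"{prefix}_{k + 1}.tsv"
        df = pd.DataFrame(data.replicates[k], columns=list(data.gene_names))
        df.insert(0, "time", data.time_grid)
        with open(path, "w") as fh:
            fh.write(head)
            df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
        paths.append(path)
    return paths


def read_expression_tables(paths) -> ExpressionDataset:
    """Assemble an :class:`ExpressionDataset` from replicate TSV files.

    All files must share the same gene columns and time grid; violations are
    reported with the offending file named.
    """
    paths = [Path(p) for p in (paths if not isinstance(paths, (str, Path)) else [paths])]
    if not paths:
        raise ValueError("no input files given")
    reps, ref_genes, ref_time = [], None, None
    for path in paths:
        try:
            df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        except Exception as exc:
            raise ValueError(f"{path}: cannot parse as tab-separated table ({exc})") from exc
        if "time" not in df.columns:
            raise ValueError(f"{path}: missing required 'time' column")
        genes = tuple(c for c in df.columns if c != "time")
        if not genes:
            raise ValueError(f"{path}: no gene columns")
        if not all(np.issubdtype(df[c].dtype, np.number) for c in df.columns):
            bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
            raise ValueError(f"{path}: non-numeric cells in column(s) {bad}")
        time = df["time"].to_numpy(float)
        if np.any(np.diff(time) <= 0):
            raise ValueError(f"{path}: time points must be strictly increasing (no duplicates)")
        if ref_genes is None:
            ref_genes, ref_time = genes, time
        else:
            if genes != ref_genes:
                raise ValueError(
                    f"{path}: gene columns {list(genes)} do not match {list(ref_genes)}"
                )
            if time.shape != ref_time.shape or not np.allclose(time, ref_time):
                raise ValueError(f"{path}: time grid differs from {paths[0]}")
        values = df[list(genes)].to_numpy(float)
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            t_bad = int(np.argwhere(~(np.isfinite(values) & (values >= 0)))[0][0])
            raise ValueError(f"{path}: non-finite or negative expression value at row {t_bad}")
        reps.append(values)
    return ExpressionDataset(
        time_grid=ref_time, replicates=np.stack(reps), gene_names=ref_genes
    )


def normalize_by_column_mean(data: ExpressionDataset) -> ExpressionDataset:
    """Divide each gene's values by that gene's mean over time, per replicate.

    The preprocessing applied to promoter-activity-style experimental
    intensity tables, bringing every gene onto an O(1) scale with mean
    exactly 1.
    """
    means = data.replicates.mean(axis=1, keepdims=True)
    if np.any(means == 0):
        bad = [data.gene_names[i] for i in np.argwhere(means == 0)[:, 2]]
        raise ValueError(f"zero column mean for gene(s) {bad}; cannot normalize")
    return ExpressionDataset(
        time_grid=data.time_grid,
        replicates=data.replicates / means,
        gene_names=data.gene_names,
    )


# ---------------------------------------------------------------------------
# result serialisation
# ---------------------------------------------------------------------------


def network_to_dict(net: IdentifiedNetwork) -> dict:
    return {
        "lam": net.lam.lam.tolist(),
        "rho": net.fit.rho.tolist(),
        "alpha": net.fit.alpha.tolist(),
        "beta": net.fit.beta.tolist(),
        "chi": net.fit.chi,
        "converged": net.fit.converged,
        "feasible": net.feasible,
        "n_connections": net.n_connections,
        "seed": net.seed,
        "per_generation_best": list(net.per_generation_best),
    }


def write_network_json(net: IdentifiedNetwork, path, *, config=None, extra=None) -> None:
    doc = network_to_dict(net)
    if config is not None:
        doc["config"] = {k: v for k, v in vars(config).items()}
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, default=float) + "\n")


def write_edge_list(
    edges, gene_names, path, *, g=None, freq=None
) -> None:
    """Tab-separated edge list: regulator, target, g_ij [, frequency]."""
    lines = ["regulator\ttarget\tg\tfrequency" if freq is not None else "regulator\ttarget\tg"]
    for i, j in sorted(edges):
        gij = "" if g is None else f"{g[i][j] if isinstance(g, dict) else g[i, j]:.6g}"
        row = f"{gene_names[j]}\t{gene_names[i]}\t{gij}"
        if freq is not None:
            row += f"\t{freq[i, j]:.4f}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def write_ensemble_summary(ensemble: NetworkEnsemble, gene_names, path) -> None:
    """Tab-separated per-connection bootstrap counts and frequencies."""
    lines = ["regulator\ttarget\tcount\tfrequency"]
    n = ensemble.freq.shape[0]
    for i in range(n):
        for j in range(n):
            count = int(round(ensemble.freq[i, j] * ensemble.n_boot))
            if count:
                lines.append(
                    f"{gene_names[j]}\t{gene_names[i]}\t{count}\t{ensemble.freq[i, j]:.4f}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_robust_json(robust: RobustNetwork, gene_names, path) -> None:
    doc = {
        "threshold": robust.threshold,
        "confidence_level": robust.confidence_level,
        "edges": [
            {
                "regulator": gene_names[j],
                "target": gene_names[i],
                "g_mean": robust.param_estimates.get((i, j), (None,) * 3)[0],
                "g_lo": robust.param_estimates.get((i, j), (None,) * 3)[1],
                "g_hi": robust.param_estimates.get((i, j), (None,) * 3)[2],
            }
            for i, j in sorted(robust.edges)
        ],
        "rates": {
            name: {
                gene_names[i]: {"mean": v[0], "lo": v[1], "hi": v[2]}
                for i, v in est.items()
            }
            for name, est in robust.rate_estimates.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=float) + "\n")


def write_manifest(path, *, command: str, seed: int, config=None, inputs=None, outputs=None) -> None:
    """Machine-readable record sufficient to reproduce a CLI run."""
    import numpy
    import scipy

    from . import __version__

    doc = {
        "command": command,
        "seed": seed,
        "config": None if config is None else {k: v for k, v in vars(config).items()},
        "inputs": [str(p) for p in (inputs or [])],
        "outputs": [str(p) for p in (outputs or [])],
        "versions": {
            "ssgrn": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=float) + "\n")
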