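"""Reading and writing of expression matrices, clinical tables and results.

Supported expression dialects: plain ``tsv``/``csv`` (first column = probe
ids, header row = sample ids) and the read-only ``geo-series-matrix`` text
dialect ("!"-prefixed metadata lines, an optional table begin/end marker
pair, quoted identifiers).
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneRanking, Signature, SurvivalData

logger = logging.getLogger(__name__)

_DELIMS = {"tsv": "\t", "csv": ","}


def _frame_to_matrix(df: pd.DataFrame) -> ExpressionMatrix:
    probes = [str(p) for p in df.index]
    dup = pd.Index(probes)[pd.Index(probes).duplicated()]
    if len(dup):
        raise ValueError(f"duplicated probe id: {dup[0]!r}")
    samples = [str(s) for s in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression value: {exc}") from exc
    if np.any(pd.isna(values)):
        raise ValueError("missing expression values are not supported")
    return ExpressionMatrix(probes, samples, values)


def read_expression(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Load a probes-by-samples expression matrix.

    Raises ``ValueError`` on duplicate identifiers, non-numeric cells or an
    empty table — malformed inputs are never silently repaired.
    """
    path = Path(path)
    if dialect in _DELIMS:
        # pandas silently renames duplicated header entries, so check first
        with path.open() as fh:
            header = fh.readline().rstrip("\n").split(_DELIMS[dialect])
        samples = [h.strip('"') for h in header[1:]]
        if len(set(samples)) != len(samples):
            dup = next(s for s in samples if samples.count(s) > 1)
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        df = pd.read_csv(path, sep=_DELIMS[dialect], index_col=0)
    elif dialect == "geo-series-matrix":
        lines = []
        for line in path.read_text().splitlines():
            stripped = line.strip()
            if not stripped or stripped.startswith("!"):
                continue
            lines.append(line)
        if not lines:
            raise ValueError(f"{path}: no table rows found in series-matrix file")
        df = pd.read_csv(_io.StringIO("\n".join(lines)), sep="\t", index_col=0)
        df.index = df.index.map(lambda p: str(p).strip('"'))
        df.columns = [str(c).strip('"') for c in df.columns]
    else:
        raise ValueError(f"unknown expression dialect {dialect!r}")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    return _frame_to_matrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path, dialect: str = "tsv") -> None:
    path = Path(path)
    df = pd.DataFrame(expr.values, index=expr.probe_ids, columns=expr.sample_ids)
    if dialect in _DELIMS:
        df.to_csv(path, sep=_DELIMS[dialect], index_label="probe_id")
    elif dialect == "geo-series-matrix":
        with path.open("w") as fh:
            fh.write("!Series_title\t\"synthetic export\"\n")
            fh.write("!series_matrix_table_begin\n")
            fh.write("\"ID_REF\"\t" + "\t".join(f'"{s}"' for s in expr.sample_ids) + "\n")
            for probe, row in zip(expr.probe_ids, expr.values):
                fh.write(f'"{probe}"\t' + "\t".join(repr(float(v)) for v in row) + "\n")
            fh.write("!series_matrix_table_end\n")
    else:
        raise ValueError(f"unknown expression dialect {dialect!r}")


def read_clinical(
    path: str | Path,
    event_mapping: Mapping[str, int] | None = None,
) -> SurvivalData:
    """Load a clinical table with columns ``sample_id``, ``time``, ``event``.

    ``event_mapping`` optionally maps string codes (e.g. ``dead``/``alive``)
    onto {1, 0}; without it the event column must already be 0/1.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"sample_id", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical column(s) {sorted(missing)}")
    ids = df["sample_id"].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"duplicate sample id: {ids[ids.duplicated()].iloc[0]!r}")
    try:
        time = df["time"].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"unparseable time value: {exc}") from exc
    event_col = df["event"]
    if event_mapping is not None:
        mapped = event_col.astype(str).str.strip().map(event_mapping)
        if mapped.isna().any():
            bad = event_col[mapped.isna()].iloc[0]
            raise ValueError(f"event value {bad!r} not covered by the mapping")
        event = mapped.to_numpy(dtype=int)
    else:
        try:
            event = event_col.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"unparseable event value: {exc}") from exc
    return SurvivalData(ids.tolist(), time, event)


def write_clinical(surv: SurvivalData, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": surv.sample_ids, "time": surv.time, "event": surv.event}
    ).to_csv(path, sep="\t", index=False)


def align(expr: ExpressionMatrix, surv: SurvivalData) -> tuple[ExpressionMatrix, SurvivalData]:
    """Restrict both inputs to shared samples, in lexicographic sample order.

    The lexicographic order is canonical: every downstream per-sample vector
    is positional over it. Dropped ids are logged; an empty intersection is
    an error.
    """
    shared = sorted(set(expr.sample_ids) & set(surv.sample_ids))
    if not shared:
        raise ValueError("no shared sample ids between expression and clinical data")
    if len(shared) < 2:
        raise ValueError("need at least 2 shared samples")
    dropped_expr = sorted(set(expr.sample_ids) - set(shared))
    dropped_surv = sorted(set(surv.sample_ids) - set(shared))
    if dropped_expr:
        msg = f"dropping {len(dropped_expr)} expression-only sample(s): {dropped_expr[:5]}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if dropped_surv:
        msg = f"dropping {len(dropped_surv)} clinical-only sample(s): {dropped_surv[:5]}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    col_idx = [expr.sample_ids.index(s) for s in shared]
    expr_out = ExpressionMatrix(list(expr.probe_ids), shared, expr.values[:, col_idx])
    row_idx = [surv.sample_ids.index(s) for s in shared]
    surv_out = SurvivalData(shared, surv.time[row_idx], surv.event[row_idx])
    return expr_out, surv_out


def write_signatures(signatures: list[Signature], path: str | Path) -> None:
    """Signature table as TSV: seed, members, statistic, log10 p, importances."""
    rows = []
    for sig in signatures:
        rows.append(
            {
                "seed": sig.seed,
                "members": ",".join(sig.members),
                "statistic": sig.statistic,
                "log10_p": format_log10_p(sig.log10_p),
                "importance": ",".join(
                    f"{sig.importance.get(m, float('nan')):.6g}" for m in sig.members
                ),
            }
        )
    pd.DataFrame(rows, columns=["seed", "members", "statistic", "log10_p", "importance"]).to_csv(
        path, sep="\t", index=False
    )


def write_signature_report(signatures: list[Signature], path: str | Path) -> None:
    """Human-readable structured-text document, one record per signature."""
    with Path(path).open("w") as fh:
        for i, sig in enumerate(signatures, 1):
            fh.write(f"[signature {i}]\n")
            fh.write(f"seed: {sig.seed}\n")
            fh.write(f"members: {', '.join(sig.members)}\n")
            fh.write(f"statistic: {sig.statistic:.6g}\n")
            fh.write(f"log10_p: {format_log10_p(sig.log10_p)}\n")
            for m in sig.members:
                fh.write(f"importance {m}: {sig.importance.get(m, float('nan')):.6g}\n")
            fh.write("\n")


def write_stability(sample_ids: list[str], stability: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "class": stability}).to_csv(path, sep="\t", index=False)


def write_ranking(ranking: GeneRanking, path: str | Path) -> None:
    pd.DataFrame(
        {
            "probe_id": ranking.probe_ids,
            "n_signatures": ranking.n_signatures,
            "mean_importance": ranking.mean_importance,
        }
    ).to_csv(path, sep="\t", index=False)


def write_distance_matrix(labels: list[str], dm: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(dm, index=labels, columns=labels).to_csv(path, sep="\t", index_label="dichotomy")


def format_log10_p(log10_p: float, floor: float = -16.0) -> str:
    """Render log10 p, printing ``<-16`` below the machine-precision floor."""
    if log10_p < floor:
        return f"<{floor:g}"
    return f"{log10_p:.4g}"
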