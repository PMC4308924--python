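"""TSV readers and writers tying the pipeline together.

The native variant format is a tab-separated table with header-named
columns matching :class:`~cardiobayes.annotations.VariantRecord` fields;
missing values are empty cells, comments start with ``#``.  Writers emit
a deterministic column order and a comment header recording the tool
version and any run metadata; readers ignore column order.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

import cardiobayes
from cardiobayes.annotations import AnnotationError, VariantRecord
from cardiobayes.inference import ChainSet, PosteriorSummary, convergence_stats
from cardiobayes.priors import BurdenRow, BurdenTable, PriorOddsTable
from cardiobayes.prediction import Prediction

VARIANT_COLUMNS = [
    "variant_id",
    "gene",
    "syndrome",
    "variant_class",
    "domain",
    "grantham",
    "sift",
    "polyphen",
    "conservation",
    "in_control_db",
    "label",
    "lod",
]

#: Annotations a class must carry to be scorable.
_REQUIRED_BY_CLASS = {
    "missense": ("grantham", "sift", "polyphen", "conservation"),
    "inframe": (),
    "radical": (),
}


class TableFormatError(ValueError):
    pass


def config_hash(items: dict) -> str:
    text = "|".join(f"{k}={items[k]}" for k in sorted(items))
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def _header_lines(meta: dict | None) -> str:
    lines = [f"# cardiobayes {cardiobayes.__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}={value}")
    return "\n".join(lines) + "\n"


def _write_tsv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(_header_lines(meta) + buf.getvalue())


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def _opt_float(cell: str):
    return None if cell == "" else float(cell)


def read_variant_table(path) -> list[VariantRecord]:
    """Read a variant annotation TSV; validation errors carry line numbers."""
    df = _read_tsv(path)
    missing_cols = {"variant_id", "gene", "syndrome", "variant_class"} - set(df.columns)
    if missing_cols:
        raise TableFormatError(f"variant table lacks columns: {sorted(missing_cols)}")
    records, errors = [], []
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after the header line
        try:
            cls = row["variant_class"]
            for fname in _REQUIRED_BY_CLASS.get(cls, ()):
                if fname in df.columns and row.get(fname, "") == "":
                    raise AnnotationError(
                        f"{row['variant_id']}: missing required annotation {fname!r} "
                        f"for a {cls} variant"
                    )
            grantham = row.get("grantham", "")
            in_db = row.get("in_control_db", "")
            records.append(
                VariantRecord(
                    variant_id=row["variant_id"],
                    gene=row["gene"],
                    syndrome=row["syndrome"],
                    variant_class=cls,
                    domain=row.get("domain", "") or None,
                    grantham=None if grantham == "" else int(float(grantham)),
                    sift=_opt_float(row.get("sift", "")),
                    polyphen=_opt_float(row.get("polyphen", "")),
                    conservation=row.get("conservation", "") or None,
                    in_control_db=None if in_db == "" else int(in_db),
                    label=row.get("label", "") or None,
                    lod=_opt_float(row.get("lod", "")),
                )
            )
        except (AnnotationError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise TableFormatError(
            "invalid variant rows:\n" + "\n".join(errors)
        )
    return records


def write_variant_table(records: list[VariantRecord], path, meta=None) -> None:
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in VARIANT_COLUMNS})
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df = df.astype(object).where(pd.notna(df), "")
    df = df.map(lambda v: "" if v is None else v)
    _write_tsv(df, path, meta)


def read_burden_table(path) -> BurdenTable:
    df = _read_tsv(path)
    required = {"gene", "syndrome", "class_group", "case_burden", "control_burden", "source"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"burden table lacks columns: {sorted(missing)}")
    rows = [
        BurdenRow(
            gene=r["gene"],
            syndrome=r["syndrome"],
            class_group=r["class_group"],
            case_burden=float(r["case_burden"]),
            control_burden=_opt_float(r["control_burden"]),
            source=r["source"],
        )
        for _, r in df.iterrows()
    ]
    return BurdenTable(rows=rows)


def packaged_burden_table() -> BurdenTable:
    """The burden table for the published cardiac gene panels."""
    ref = importlib.resources.files("cardiobayes").joinpath("data/burden_cardiac.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_burden_table(path)


def write_prior_table(table: PriorOddsTable, path, meta=None) -> None:
    rows = [
        {
            "gene": e.gene,
            "syndrome": e.syndrome,
            "class_group": e.class_group,
            "prior_odds": e.prior_odds,
            "policy": e.policy,
        }
        for e in sorted(
            table.entries.values(), key=lambda e: (e.syndrome, e.gene, e.class_group)
        )
    ]
    _write_tsv(pd.DataFrame(rows), path, meta)


def write_summary(summary: PosteriorSummary, path, meta=None) -> None:
    rows = [
        {
            "parameter": name,
            "median": summary.median[name],
            "q05": summary.q05[name],
            "q95": summary.q95[name],
        }
        for name in summary.median
    ]
    _write_tsv(pd.DataFrame(rows), path, meta)


def read_summary(path) -> PosteriorSummary:
    df = _read_tsv(path)
    return PosteriorSummary(
        median={r["parameter"]: float(r["median"]) for _, r in df.iterrows()},
        q05={r["parameter"]: float(r["q05"]) for _, r in df.iterrows()},
        q95={r["parameter"]: float(r["q95"]) for _, r in df.iterrows()},
    )


def write_chains(chains: ChainSet, path, meta=None) -> None:
    """Columnar chain dump: chain id, iteration, one column per parameter."""
    n_chains, n_kept = chains.n_chains, chains.n_kept
    data = {
        "chain": np.repeat(np.arange(n_chains), n_kept),
        "iteration": np.tile(np.arange(n_kept), n_chains),
    }
    for name, draws in chains.draws.items():
        data[name] = draws.ravel()
    base = dict(meta or {})
    base.update(seed=chains.seed, n_iter=chains.n_iter, burn_fraction=chains.burn_fraction)
    _write_tsv(pd.DataFrame(data), path, base)


def write_convergence(chains: ChainSet, path, meta=None) -> None:
    stats = convergence_stats(chains)
    rows = [
        {"parameter": s.parameter, "W": s.W, "B": s.B, "var_hat": s.var_hat, "R": s.R}
        for s in stats.values()
    ]
    _write_tsv(pd.DataFrame(rows), path, meta)


def write_predictions(preds: list[Prediction], path, meta=None) -> None:
    rows = [
        {
            "variant_id": p.variant_id,
            "gene": p.gene,
            "syndrome": p.syndrome,
            "variant_class": p.variant_class,
            "probability": p.probability,
            "logit": p.logit,
            "band": p.band_label if p.band_label is not None else "",
            "lod_applied": p.lod_applied,
        }
        for p in preds
    ]
    _write_tsv(pd.DataFrame(rows), path, meta)


def write_metrics(report, path, meta=None) -> None:
    _write_tsv(report.metrics, path, meta)


def write_roc_points(report, path, meta=None) -> None:
    rows = []
    for stratum, r in report.roc_points.items():
        for fpr, tpr, thr in zip(r.fpr, r.tpr, r.thresholds):
            rows.append(
                {"stratum": stratum, "threshold": thr, "fpr": fpr, "tpr": tpr,
                 "auc": r.area}
            )
    _write_tsv(pd.DataFrame(rows), path, meta)
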