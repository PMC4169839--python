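"""Reading and writing of genotype, phenotype and result tables.

All formats are plain CSV/TSV (delimiter chosen by file suffix, ``.tsv`` or
``.txt`` meaning tab).  Floats are written with 17 significant digits so
reader/writer round trips preserve values bit-for-bit.

Expected layouts
----------------
genotypes
    header ``marker_id, chromosome, position_cM`` followed by one column
    per line holding donor dosages 0/1/2.
phenotypes (line means)
    columns ``line_id, value``.
phenotypes (plot values)
    columns ``line_id, <design factors...>, plot_value`` — one row per
    field plot; design factors (location, year, replication, tester, ...)
    may be adjusted out with :func:`adjust_plot_values`.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import ModelFit, PhenotypeVector
from .segments import (
    GenotypeValidationError,
    MarkerGenotypes,
    SegmentMap,
    render_graphical_genotypes,
)
from .significance import SegmentTestResult

__all__ = [
    "PlotTable",
    "read_genotypes",
    "read_phenotypes",
    "write_genotypes",
    "write_phenotypes",
    "write_segment_map",
    "write_effects",
    "write_test_results",
    "adjust_plot_values",
    "align_design",
]

FLOAT_FMT = "%.17g"


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


@dataclasses.dataclass
class PlotTable:
    """Plot-level phenotype records with experimental design factors."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("line_id", "plot_value"):
            if col not in df.columns:
                raise ValueError(f"plot table lacks required column {col!r}")
        if df["plot_value"].isna().any() or df[self.factor_columns].isna().any().any():
            raise ValueError("plot table contains missing values")
        if not np.issubdtype(df["plot_value"].dtype, np.number):
            raise ValueError("plot_value column must be numeric")
        self.data = df.assign(line_id=df["line_id"].astype(str))

    @property
    def factor_columns(self) -> list:
        return [c for c in self.data.columns if c not in ("line_id", "plot_value")]

    @property
    def line_ids(self) -> list:
        return list(dict.fromkeys(self.data["line_id"]))


def read_genotypes(path) -> MarkerGenotypes:
    """Read a marker genotype table (markers in rows, lines in columns)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    required = ["marker_id", "chromosome", "position_cM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GenotypeValidationError(
            f"{path}: missing required column(s) {missing}"
        )
    line_cols = [c for c in df.columns if c not in required]
    if not line_cols:
        raise GenotypeValidationError(f"{path}: no line dosage columns found")
    for c in line_cols:
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any():
            row = df.loc[col.isna(), "marker_id"].iloc[0]
            raise GenotypeValidationError(
                f"{path}: non-numeric dosage in column {c!r} at marker {row!r}"
            )
        df[c] = col
    try:
        return MarkerGenotypes(
            line_ids=line_cols,
            markers=df[required],
            dosage=df[line_cols].to_numpy().T,
        )
    except GenotypeValidationError as err:
        raise GenotypeValidationError(f"{path}: {err}") from None


def write_genotypes(geno: MarkerGenotypes, path) -> None:
    path = Path(path)
    df = geno.markers.copy()
    for i, line in enumerate(geno.line_ids):
        df[line] = geno.dosage[i]
    df.to_csv(path, sep=_sep(path), index=False, float_format=FLOAT_FMT)


def read_phenotypes(path) -> PhenotypeVector | PlotTable:
    """Read line-mean phenotypes (``line_id,value``) or a plot-value table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    if "line_id" not in df.columns:
        raise ValueError(f"{path}: phenotype table lacks a line_id column")
    if "plot_value" in df.columns:
        try:
            return PlotTable(df)
        except ValueError as err:
            raise ValueError(f"{path}: {err}") from None
    if "value" not in df.columns:
        raise ValueError(
            f"{path}: expected a 'value' (line means) or 'plot_value' column"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        bad = df.loc[values.isna(), "line_id"].iloc[0]
        raise ValueError(f"{path}: non-numeric phenotype for line {bad!r}")
    return PhenotypeVector(line_ids=list(df["line_id"].astype(str)), values=values)


def write_phenotypes(pheno: PhenotypeVector | PlotTable, path) -> None:
    path = Path(path)
    if isinstance(pheno, PlotTable):
        pheno.data.to_csv(path, sep=_sep(path), index=False, float_format=FLOAT_FMT)
        return
    pd.DataFrame({"line_id": pheno.line_ids, "value": pheno.values}).to_csv(
        path, sep=_sep(path), index=False, float_format=FLOAT_FMT
    )


def align_design(design, pheno: PhenotypeVector):
    """Expand/reorder design rows to match a phenotype vector's line ids.

    Raises a ``KeyError`` listing any phenotype line id absent from the
    design (the explicit join report lives in the message).
    """
    known = set(design.row_ids)
    unknown = sorted({l for l in pheno.line_ids if l not in known})
    if unknown:
        raise KeyError(
            f"phenotype line id(s) {unknown} absent from the genotype table"
        )
    return design.expand(pheno.line_ids)


def adjust_plot_values(
    plots: PlotTable, factors: list[str] | None = None
) -> tuple[PhenotypeVector, dict]:
    """Adjust plot values for design factors and average per line.

    The named factors (replication, year, location, ...) are fitted as
    fixed effects by ordinary least squares *without* any genotype term;
    each plot value is corrected to ``residual + grand mean`` and the
    corrected values are averaged per line.  In a balanced design this
    recovers the true line means exactly (up to recentring at the grand
    mean).  Returns the per-line adjusted means and a dict of per-line
    plot counts.

    Analysing such adjusted plot values instead of entry means keeps the
    pure experimental error in the model's residual variance, which the
    segment significance tests then estimate more faithfully.
    """
    import statsmodels.formula.api as smf

    factors = list(factors or [])
    df = plots.data
    for f in factors:
        if f not in plots.factor_columns:
            raise ValueError(f"{f!r} is not a factor column of the plot table")
        levels = df.groupby(f)["line_id"].nunique()
        lonely = levels[levels < 2]
        if len(lonely):
            warnings.warn(
                f"factor {f!r} has level(s) {list(lonely.index)} observed on "
                "a single line; factor and line effects are confounded there",
                RuntimeWarning,
                stacklevel=2,
            )
    if factors:
        formula = "plot_value ~ " + " + ".join(f"C(Q('{f}'))" for f in factors)
        model = smf.ols(formula, data=df).fit()
        adjusted = model.resid + df["plot_value"].mean()
    else:
        adjusted = df["plot_value"].astype(float)
    work = pd.DataFrame({"line_id": df["line_id"], "adj": adjusted})
    grouped = work.groupby("line_id", sort=False)["adj"]
    means = grouped.mean()
    counts = grouped.size().to_dict()
    return (
        PhenotypeVector(line_ids=list(means.index), values=means.to_numpy()),
        counts,
    )


def write_segment_map(smap: SegmentMap, path, graphical_path=None) -> None:
    """Write the segment table (TSV/CSV); optionally a graphical genotype."""
    path = Path(path)
    smap.to_frame().to_csv(path, sep=_sep(path), index=False, float_format=FLOAT_FMT)
    if graphical_path is not None and smap.source is not None:
        Path(graphical_path).write_text(render_graphical_genotypes(smap.source))


def _segment_coords(smap: SegmentMap | None, segment_id: str) -> dict:
    if smap is None:
        return {"chromosome": "", "start_cM": "", "end_cM": ""}
    for s in smap.segments:
        if s.segment_id == segment_id:
            return {
                "chromosome": s.chromosome,
                "start_cM": s.start_cM,
                "end_cM": s.end_cM,
            }
    return {"chromosome": "", "start_cM": "", "end_cM": ""}


def write_effects(fit: ModelFit, path, smap: SegmentMap | None = None) -> None:
    """Write estimated segment effects with model-level header comments."""
    path = Path(path)
    lam = fit.lambdas if fit.lambdas is not None else (
        np.full(fit.n_segments, fit.lambda_) if fit.lambda_ is not None else
        np.full(fit.n_segments, np.nan)
    )
    rows = []
    for sid, u, l in zip(fit.segment_ids, fit.effects, lam):
        row = {"segment_id": sid}
        row.update(_segment_coords(smap, sid))
        row.update({"method": fit.method, "effect": u, "lambda_i": l})
        rows.append(row)
    header = [
        f"# method={fit.method}",
        f"# beta0={'' if fit.intercept is None else FLOAT_FMT % fit.intercept}",
        f"# sigma2_e={FLOAT_FMT % fit.sigma2_e}",
        f"# sigma2_u={'' if fit.sigma2_u is None else FLOAT_FMT % fit.sigma2_u}",
        f"# lambda={'' if fit.lambda_ is None else FLOAT_FMT % fit.lambda_}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        pd.DataFrame(rows).to_csv(
            fh, sep=_sep(path), index=False, float_format=FLOAT_FMT
        )


def write_test_results(
    results: list[SegmentTestResult],
    path,
    smap: SegmentMap | None = None,
    method: str = "",
) -> None:
    path = Path(path)
    rows = []
    for r in results:
        row = {"segment_id": r.segment_id}
        row.update(_segment_coords(smap, r.segment_id))
        row.update(
            {
                "method": method,
                "effect": r.effect,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
            }
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False, float_format=FLOAT_FMT)
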