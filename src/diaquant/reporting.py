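"""Result tables, the 2D iBAQ-decile color code, the standalone HTML
report and the all-in-one pipeline runner.

The report is a single self-contained HTML file (styles and figures
inlined, no network access needed) with a fixed section order; tables are
written both as spreadsheets with color annotation and as plain TSV
twins.  The all-in-one runner executes ingest -> preprocess -> quantify ->
stats -> qc -> report under a fixed numbered folder layout and is
resumable per stage.
"""
from __future__ import annotations

import base64
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from openpyxl import Workbook
from openpyxl.styles import PatternFill

from . import __version__
from .config import PipelineConfig
from .datamodel import PeptideMatrix, PrecursorTable, ProteinQuantTable, StudyDesign

logger = logging.getLogger(__name__)

STAGE_DIRS = ["01_ingest", "02_preprocess", "03_quant", "04_stats", "05_qc", "06_report"]

STAT_COLUMNS = [
    "protein_group",
    "n_peptides_tested",
    "median_log2_ratio",
    "protein_p",
    "adj_p",
    "effect_size",
    "decile_A",
    "decile_B",
    "2d_code",
]


# ---------------------------------------------------------------------------
# color codes

def decile_color(decile_a: int, decile_b: int) -> str:
    """Two-axis gradient hex color for a (decile_A, decile_B) pair.

    Axis A drives the red channel, axis B the blue channel; both run from
    dim (decile 1) to saturated (decile 10).
    """
    if not (1 <= decile_a <= 10 and 1 <= decile_b <= 10):
        raise ValueError("deciles must be in 1..10")
    r = int(round(55 + 200 * (decile_a - 1) / 9))
    b = int(round(55 + 200 * (decile_b - 1) / 9))
    return f"#{r:02X}50{b:02X}"


def log2fc_color(value: float, bound: float = 2.0) -> str:
    """Signed three-point gradient (blue .. white .. red), saturating at +-bound."""
    if not np.isfinite(value):
        return "#FFFFFF"
    x = float(np.clip(value / bound, -1.0, 1.0))
    if x >= 0:
        g = b = int(round(255 * (1 - x)))
        return f"#FF{g:02X}{b:02X}"
    g = r = int(round(255 * (1 + x)))
    return f"#{r:02X}{g:02X}FF"


def decile_legend_table() -> pd.DataFrame:
    """Machine-readable (decile_A, decile_B, hexcolor) legend."""
    rows = [
        {"decile_A": a, "decile_B": b, "hexcolor": decile_color(a, b)}
        for a in range(1, 11)
        for b in range(1, 11)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics tables

def write_stat_tables(
    stats_by_comparison: dict[tuple[str, str], pd.DataFrame],
    annotation: pd.DataFrame | None,
    out_dir,
    color_bound: float = 2.0,
) -> list[Path]:
    """One spreadsheet + TSV twin per comparison, plus the decile legend.

    Spreadsheet cells carry the 2D decile color (on the 2d_code column)
    and the signed log2-ratio gradient; a legend sheet maps every decile
    pair to its fill color.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    legend = decile_legend_table()
    legend_path = out_dir / "ibaq_decile_colors.tsv"
    legend.to_csv(legend_path, sep="\t", index=False)
    written.append(legend_path)

    for (num, den), stats in stats_by_comparison.items():
        name = f"statistics_{num}_vs_{den}"
        if annotation is not None and not stats.empty:
            missing = set(stats["protein_group"]) - set(annotation.index)
            if missing:
                raise ValueError(
                    f"proteins in statistics but not in decile annotation: {sorted(missing)[:10]}"
                )
        table = stats.copy()
        for col in STAT_COLUMNS:
            if col not in table.columns:
                table[col] = pd.NA
        table = table[STAT_COLUMNS]
        tsv_path = out_dir / f"{name}.tsv"
        table.to_csv(tsv_path, sep="\t", index=False)
        written.append(tsv_path)

        wb = Workbook()
        ws = wb.active
        ws.title = "statistics"
        ws.append(STAT_COLUMNS)
        for _, row in table.iterrows():
            ws.append([None if pd.isna(v) else v for v in row])
            r = ws.max_row
            fc = row["median_log2_ratio"]
            if pd.notna(fc):
                ws.cell(row=r, column=STAT_COLUMNS.index("median_log2_ratio") + 1).fill = PatternFill(
                    "solid", fgColor=log2fc_color(float(fc), color_bound).lstrip("#")
                )
            da, db = row["decile_A"], row["decile_B"]
            if pd.notna(da) and pd.notna(db):
                ws.cell(row=r, column=STAT_COLUMNS.index("2d_code") + 1).fill = PatternFill(
                    "solid", fgColor=decile_color(int(da), int(db)).lstrip("#")
                )
        leg = wb.create_sheet("decile_legend")
        leg.cell(row=1, column=1, value="decile_A \\ decile_B")
        for b in range(1, 11):
            leg.cell(row=1, column=b + 1, value=b)
        for a in range(1, 11):
            leg.cell(row=a + 1, column=1, value=a)
            for b in range(1, 11):
                cell = leg.cell(row=a + 1, column=b + 1, value=decile_color(a, b))
                cell.fill = PatternFill("solid", fgColor=decile_color(a, b).lstrip("#"))
        xlsx_path = out_dir / f"{name}.xlsx"
        wb.save(xlsx_path)
        written.append(xlsx_path)
    return written


# ---------------------------------------------------------------------------
# HTML report

@dataclass
class ReportSection:
    title: str
    html: str = ""
    skipped: bool = False


@dataclass
class ReportBundle:
    output_root: Path
    sections: list[ReportSection] = field(default_factory=list)
    run_parameters: dict = field(default_factory=dict)
    software_versions: dict = field(default_factory=dict)
    title: str = "DIA-MS quantification report"

    def add(self, title: str, html: str = "", skipped: bool = False) -> None:
        self.sections.append(ReportSection(title, html, skipped))


def fig_to_html(fig) -> str:
    """Inline a matplotlib figure as a base64 <img> (self-contained HTML)."""
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110, bbox_inches="tight",
                metadata={"Software": None})  # no writer stamp: byte-stable output
    plt.close(fig)
    return '<img src="data:image/png;base64,{}"/>'.format(
        base64.b64encode(buf.getvalue()).decode()
    )


def df_to_html(df: pd.DataFrame, max_rows: int = 25) -> str:
    shown = df.head(max_rows)
    note = ""
    if len(df) > max_rows:
        note = f"<p class='note'>showing {max_rows} of {len(df)} rows</p>"
    return shown.to_html(index=False, border=0, float_format=lambda x: f"{x:.4g}") + note


_CSS = """
body { font-family: sans-serif; margin: 2em auto; max-width: 1100px; color: #222; }
h1 { border-bottom: 2px solid #444; }
h2 { color: #2a5d8f; margin-top: 2em; }
table { border-collapse: collapse; font-size: 0.85em; }
th, td { padding: 3px 9px; border-bottom: 1px solid #ddd; text-align: right; }
th { background: #f0f4f8; }
.note { color: #777; font-size: 0.8em; }
.skipped { color: #999; font-style: italic; }
"""


def render_html_report(bundle: ReportBundle, filename: str = "report.html") -> Path:
    """Write one self-contained HTML file; missing sections say "not computed"."""
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>{bundle.title}</title><style>{_CSS}</style></head><body>",
        f"<h1>{bundle.title}</h1>",
    ]
    parts.append("<h2>Run parameters</h2><table><tr><th>parameter</th><th>value</th></tr>")
    for k in sorted(bundle.run_parameters):
        parts.append(f"<tr><td>{k}</td><td>{bundle.run_parameters[k]}</td></tr>")
    parts.append("</table>")
    for sec in bundle.sections:
        parts.append(f"<h2>{sec.title}</h2>")
        if sec.skipped or not sec.html:
            parts.append("<p class='skipped'>not computed</p>")
        else:
            parts.append(sec.html)
    parts.append("<h2>Software</h2><table><tr><th>component</th><th>version</th></tr>")
    for k in sorted(bundle.software_versions):
        parts.append(f"<tr><td>{k}</td><td>{bundle.software_versions[k]}</td></tr>")
    parts.append("</table></body></html>")
    out = Path(bundle.output_root) / filename
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text("\n".join(parts))
    return out


# ---------------------------------------------------------------------------
# all-in-one pipeline

def _stage_done(stage_dir: Path) -> bool:
    return (stage_dir / ".done").exists()


def _mark_done(stage_dir: Path) -> None:
    (stage_dir / ".done").write_text("ok\n")


def all_in_one(
    report,
    design,
    fasta=None,
    config: PipelineConfig | None = None,
    out="diaquant_out",
    resume: bool = False,
) -> ReportBundle:
    """Execute the full pipeline and write every intermediate + the report.

    Folder layout is fixed: 01_ingest/ 02_preprocess/ 03_quant/ 04_stats/
    05_qc/ 06_report/.  With ``resume=True``, stages whose .done marker
    exists are recomputed in memory but their files are not rewritten.
    Any stage's hard error aborts with the stage name.
    """
    from . import io_ingest, multivariate_qc, preprocess, protein_quant, stats as stats_mod

    config = config or PipelineConfig()
    out = Path(out)
    dirs = {name[3:]: out / name for name in STAGE_DIRS}
    for d in dirs.values():
        d.mkdir(parents=True, exist_ok=True)

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(
                f"pipeline aborted in stage {name!r}: {exc}; partial outputs under {out}"
            ) from exc

    # 01 ingest
    def _ingest():
        table = io_ingest.read_precursor_report(report, config.column_map)
        study = io_ingest.read_design(design)
        study.validate_against(table)
        sequences = io_ingest.read_fasta(fasta) if fasta else None
        if sequences is None and "iBAQ" in config.methods:
            raise ValueError("iBAQ requested but no FASTA given")
        summary = io_ingest.id_rate_summary(table)
        if not (resume and _stage_done(dirs["ingest"])):
            table.to_tsv(dirs["ingest"] / "precursors.tsv")
            summary.to_csv(dirs["ingest"] / "id_rate_summary.tsv", sep="\t", index=False)
            _mark_done(dirs["ingest"])
        return table, study, sequences, summary

    table, study, sequences, id_summary = run_stage("ingest", _ingest)

    # 02 preprocess
    def _preprocess():
        filt = preprocess.filter_qvalues(table, config.max_precursor_q, config.max_pg_q)
        n_ox = 0
        if config.remove_oxidized:
            filt, n_ox = preprocess.remove_oxidized_met(filt, tuple(config.oxidation_tags))
        matrix = preprocess.build_peptide_matrix(filt, study)
        matrix = preprocess.condition_wise_filter(matrix, config.min_fraction)
        if config.normalize:
            matrix = preprocess.log2_median_normalize(matrix)
        if config.adjust_batch and (study.has_batch or study.covariate_columns):
            matrix = preprocess.adjust_batch_covariates(matrix, study)
        if not (resume and _stage_done(dirs["preprocess"])):
            matrix.values.to_csv(dirs["preprocess"] / "peptide_matrix.tsv", sep="\t")
            if matrix.normalization_offsets is not None:
                matrix.normalization_offsets.rename("offset_log2").to_csv(
                    dirs["preprocess"] / "normalization_offsets.tsv", sep="\t"
                )
            pd.Series({"oxidized_precursors_removed": n_ox}).to_csv(
                dirs["preprocess"] / "filter_log.tsv", sep="\t", header=False
            )
            _mark_done(dirs["preprocess"])
        return filt, matrix, n_ox

    filtered_table, matrix, n_ox = run_stage("preprocess", _preprocess)

    # 03 quantify
    def _quantify():
        digest = protein_quant.DigestParams(
            config.digest_min_len, config.digest_max_len, config.missed_cleavages
        )
        tables = protein_quant.quantify(
            matrix, sequences, tuple(config.methods), digest, config.min_peptides_pair
        )
        annotation = None
        if "iBAQ" in tables:
            annotation = protein_quant.assign_ibaq_deciles(tables["iBAQ"], study)
        if not (resume and _stage_done(dirs["quant"])):
            for method, qt in tables.items():
                df = qt.values.copy()
                df["n_peptides"] = qt.n_peptides
                df["flags"] = [";".join(qt.flags.get(p, [])) for p in df.index]
                df.to_csv(dirs["quant"] / f"protein_{method.lower()}.tsv", sep="\t")
            if annotation is not None:
                annotation.to_csv(dirs["quant"] / "ibaq_deciles.tsv", sep="\t")
            _mark_done(dirs["quant"])
        return tables, annotation

    quant_tables, annotation = run_stage("quantify", _quantify)

    # 04 statistics
    def _stats():
        effect_table = quant_tables.get("MaxLFQ") or next(iter(quant_tables.values()), None)
        results = stats_mod.run_all_comparisons(
            matrix, config.stat_method, effect_table, annotation, config.welch
        )
        if not (resume and _stage_done(dirs["stats"])):
            write_stat_tables(results, annotation, dirs["stats"], config.log2fc_color_bound)
            _mark_done(dirs["stats"])
        return results

    stat_results = run_stage("statistics", _stats) if study.comparisons else {}

    # 05 qc
    def _qc():
        qc_out: dict = {}
        pca_source = (
            quant_tables["MaxLFQ"].values if "MaxLFQ" in quant_tables else matrix.values
        )
        try:
            qc_out["pca"] = multivariate_qc.pca(pca_source)
        except ValueError as exc:
            logger.warning("PCA skipped: %s", exc)
            qc_out["pca"] = None
        qc_out["corr"], qc_out["corr_n"] = multivariate_qc.sample_correlation(matrix.values)
        qc_out["cv"], qc_out["cv_median"] = multivariate_qc.cv_summary(matrix.linear(), study)
        qc_out["onoff"] = multivariate_qc.on_off_analysis(filtered_table, study)
        if not (resume and _stage_done(dirs["qc"])):
            if qc_out["pca"] is not None:
                qc_out["pca"].scores.to_csv(dirs["qc"] / "pca_scores.tsv", sep="\t")
                qc_out["pca"].loadings.to_csv(dirs["qc"] / "pca_loadings.tsv", sep="\t")
                qc_out["pca"].explained_variance_fraction.to_csv(
                    dirs["qc"] / "explained_variance.tsv", sep="\t"
                )
            qc_out["corr"].to_csv(dirs["qc"] / "sample_correlation.tsv", sep="\t")
            qc_out["cv_median"].to_csv(dirs["qc"] / "cv_summary.tsv", sep="\t")
            qc_out["onoff"].to_csv(dirs["qc"] / "on_off_calls.tsv", sep="\t", index=False)
            _mark_done(dirs["qc"])
        return qc_out

    qc = run_stage("qc", _qc)

    # 06 report
    def _report():
        from dataclasses import asdict

        bundle = ReportBundle(
            output_root=dirs["report"],
            run_parameters=asdict(config),
            software_versions={"diaquant": __version__},
            title=config.report_title,
        )
        bundle.add("Identification rates", df_to_html(id_summary))
        bundle.add(
            "Filtering",
            f"<p>q-value thresholds: precursor {config.max_precursor_q}, protein group "
            f"{config.max_pg_q}; oxidized precursors removed: {n_ox}; condition-wise "
            f"completeness threshold: {config.min_fraction}.</p>",
        )
        if matrix.normalization_offsets is not None:
            bundle.add(
                "Normalization offsets",
                df_to_html(
                    matrix.normalization_offsets.rename("offset_log2")
                    .rename_axis("run_id")
                    .reset_index()
                ),
            )
        else:
            bundle.add("Normalization offsets", skipped=True)
        if qc["pca"] is not None:
            fig, ax = plt.subplots(figsize=(5, 4))
            sc = qc["pca"].scores
            conds = study.samples.set_index("run_id")["condition"]
            for cond, grp in sc.groupby(conds.reindex(sc.index)):
                ax.scatter(grp["PC1"], grp.get("PC2", grp["PC1"] * 0), label=cond)
            evf = qc["pca"].explained_variance_fraction
            ax.set_xlabel(f"PC1 ({evf.iloc[0]:.1%})")
            if "PC2" in sc:
                ax.set_ylabel(f"PC2 ({evf.iloc[1]:.1%})")
            ax.legend()
            bundle.add("Multivariate analysis (PCA)", fig_to_html(fig))
        else:
            bundle.add("Multivariate analysis (PCA)", skipped=True)
        bundle.add(
            "Sample correlation",
            df_to_html(qc["corr"].round(4).rename_axis("run_id").reset_index()),
        )
        bundle.add(
            "Coefficient of variation",
            df_to_html(qc["cv_median"].rename_axis("condition").reset_index()),
        )
        onoff = qc["onoff"]
        call_cols = [c for c in onoff.columns if c.startswith("call[")]
        n_calls = int((onoff[call_cols] != "none").sum().sum()) if call_cols else 0
        bundle.add("ON/OFF analysis", f"<p>{n_calls} ON/OFF calls.</p>" + df_to_html(onoff))
        if stat_results:
            frags = []
            for (num, den), res in stat_results.items():
                n_sig = int((res["adj_p"] < config.alpha).sum()) if not res.empty else 0
                frags.append(
                    f"<h3>{num} vs {den}</h3><p>{n_sig} proteins at adjusted "
                    f"p &lt; {config.alpha}.</p>" + df_to_html(res.sort_values("adj_p") if not res.empty else res)
                )
            bundle.add("Differential statistics", "\n".join(frags))
        else:
            bundle.add("Differential statistics", skipped=True)
        bundle.add(
            "Extracted ion chromatograms",
            "<p class='skipped'>XIC rendering requires the acquisition software's "
            "chromatogram export and is not part of this pipeline.</p>",
        )
        bundle.add(
            "Methods",
            "<p>Median normalization of log2 precursor intensities; protein "
            "quantification by iBAQ (summed intensity over theoretically observable "
            "tryptic peptides), Hi3 (mean of three most intense precursors) and "
            "MaxLFQ (pairwise-ratio least squares); peptide-centric differential "
            "statistics with empirical-Bayes moderated t tests aggregated per "
            "protein via the median p-value order statistic; Benjamini-Hochberg "
            "adjustment across proteins per comparison.</p>",
        )
        if not (resume and _stage_done(dirs["report"])):
            config.to_file(dirs["report"] / "run_parameters.yaml")
            render_html_report(bundle)
            _mark_done(dirs["report"])
        return bundle

    return run_stage("report", _report)
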