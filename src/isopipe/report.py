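"""Plain-text report assembly.

Pulls the result tables of the individual pipeline stages into one
human-readable summary: flattened-model feature totals, differential-usage
results at several thresholds, theoretical-isoform counts, and the ROI
classification breakdown.  Missing inputs produce a warning and an omitted
section rather than an error, so partial runs still report."""

from __future__ import annotations

import warnings

import pandas as pd

from . import __version__


def _frame_block(frame: pd.DataFrame, float_format: str = "%.4g") -> str:
    return frame.to_string(index=False, float_format=lambda v: float_format % v)


def build_report(
    model_summary: pd.DataFrame | None = None,
    gene_table: pd.DataFrame | None = None,
    threshold_table: pd.DataFrame | None = None,
    enumeration: dict[str, int] | None = None,
    roi_tables: dict[str, pd.DataFrame] | None = None,
    title: str = "isopipe analysis report",
) -> str:
    """Assemble the report text from whichever stage outputs are present."""
    lines = [title, "=" * len(title), f"isopipe version {__version__}", ""]

    sections = []
    if model_summary is not None:
        sections.append(
            ("Flattened gene models (regions / known / novel junctions)",
             _frame_block(model_summary))
        )
    if threshold_table is not None:
        sections.append(
            ("Differential usage by adjusted-p threshold", _frame_block(threshold_table))
        )
    if gene_table is not None:
        sections.append(
            ("Gene-wise differential usage", _frame_block(gene_table))
        )
    if enumeration is not None:
        body = "\n".join(f"{key}: {value}" for key, value in enumeration.items())
        sections.append(("Theoretical isoform enumeration", body))
    if roi_tables is not None:
        body = "\n\n".join(
            f"[{name}]\n{_frame_block(frame)}" for name, frame in roi_tables.items()
        )
        sections.append(("ROI classification", body))

    expected = ("model_summary", "gene_table", "threshold_table", "enumeration", "roi_tables")
    provided = (model_summary, gene_table, threshold_table, enumeration, roi_tables)
    missing = [name for name, value in zip(expected, provided) if value is None]
    if missing:
        warnings.warn(f"report sections omitted (no input): {', '.join(missing)}")

    for heading, body in sections:
        lines.extend([heading, "-" * len(heading), body, ""])
    return "\n".join(lines)


def model_summary_frame(models: list) -> pd.DataFrame:
    """One row per flattened gene model: counts of regions and junctions."""
    rows = [
        {
            "gene_id": m.gene_id,
            "exonic_regions": len(m.exonic_regions),
            "known_junctions": len(m.known_junctions),
            "novel_junctions": len(m.novel_junctions),
        }
        for m in models
    ]
    return pd.DataFrame(rows)
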