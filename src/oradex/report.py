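"""Tidy report tables behind the dashboard views.

Everything derives from the unfiltered candidate-pair table joined to note
metadata: opioid-class and per-drug patient counts, per-(drug, PT/LLT)
patient counts with top-k adverse events per drug, brand/generic splits, a
drug x AE chord matrix whose marginals agree with the pair counts, optional
demographic summaries, and a per-patient line listing.  Report generation
is read-only over its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from oradex.corpus_io import NoteRecord
from oradex.pairing import CandidateORADE, unfiltered

logger = logging.getLogger(__name__)


@dataclass
class ReportBundle:
    class_counts: pd.DataFrame
    drug_counts: pd.DataFrame
    drug_ae_counts: pd.DataFrame
    top_ae_per_drug: pd.DataFrame
    brand_generic_counts: pd.DataFrame
    chord_matrix: pd.DataFrame
    patient_lines: pd.DataFrame
    demographics_summary: Optional[dict[str, pd.DataFrame]] = None


def _unit_column(df: pd.DataFrame, count_notes: bool) -> str:
    return "note_id" if count_notes else "subject_id"


def build_report(
    pairs: Sequence[CandidateORADE],
    notes: Sequence[NoteRecord],
    demographics: Optional[pd.DataFrame] = None,
    top_k: int = 3,
    count_notes: bool = False,
    age_bin_width: int = 10,
) -> ReportBundle:
    """Aggregate unfiltered pairs into the report tables.

    Counts are over unique patients (``subject_id``) unless ``count_notes``
    is set.  Top-k adverse-event lists per drug break ties by descending
    count, then alphabetical preferred term.
    """
    subject_of = {n.note_id: n.subject_id for n in notes}
    rows = [
        {
            "note_id": p.note_id,
            "subject_id": subject_of.get(p.note_id, p.note_id),
            "generic_drug": p.generic_drug,
            "drug_class": p.drug_class,
            "drug_kind": p.drug_kind,
            "ae_pt": p.ae_pt,
            "ae_llt": p.ae_llt or "",
        }
        for p in unfiltered(pairs)
    ]
    df = pd.DataFrame(
        rows,
        columns=["note_id", "subject_id", "generic_drug", "drug_class", "drug_kind", "ae_pt", "ae_llt"],
    )
    unit = _unit_column(df, count_notes)

    def nunique_by(*cols: str) -> pd.DataFrame:
        if df.empty:
            return pd.DataFrame(columns=[*cols, "count"])
        out = df.groupby(list(cols))[unit].nunique().reset_index(name="count")
        return out.sort_values(["count", *cols], ascending=[False] + [True] * len(cols)).reset_index(drop=True)

    class_counts = nunique_by("drug_class")
    drug_counts = nunique_by("generic_drug")
    drug_ae_counts = nunique_by("generic_drug", "ae_pt", "ae_llt")
    brand_generic_counts = nunique_by("drug_kind")

    if drug_ae_counts.empty:
        top_ae = pd.DataFrame(columns=["generic_drug", "rank", "ae_pt", "count"])
    else:
        per_drug = drug_ae_counts.groupby(["generic_drug", "ae_pt"], as_index=False)["count"].max()
        per_drug = per_drug.sort_values(
            ["generic_drug", "count", "ae_pt"], ascending=[True, False, True]
        )
        per_drug["rank"] = per_drug.groupby("generic_drug").cumcount() + 1
        top_ae = per_drug[per_drug["rank"] <= top_k][["generic_drug", "rank", "ae_pt", "count"]]
        top_ae = top_ae.reset_index(drop=True)

    if df.empty:
        chord = pd.DataFrame()
    else:
        chord = (
            df.groupby(["generic_drug", "ae_pt"])[unit]
            .nunique()
            .unstack(fill_value=0)
            .sort_index(axis=0)
            .sort_index(axis=1)
        )

    patient_lines = (
        df[["subject_id", "generic_drug", "ae_pt", "note_id"]]
        .drop_duplicates()
        .sort_values(["subject_id", "generic_drug", "ae_pt", "note_id"])
        .reset_index(drop=True)
    )

    demo_summary = None
    if demographics is not None:
        demo_summary = _summarize_demographics(demographics, df, age_bin_width)

    return ReportBundle(
        class_counts=class_counts,
        drug_counts=drug_counts,
        drug_ae_counts=drug_ae_counts,
        top_ae_per_drug=top_ae,
        brand_generic_counts=brand_generic_counts,
        chord_matrix=chord,
        patient_lines=patient_lines,
        demographics_summary=demo_summary,
    )


def _summarize_demographics(
    demographics: pd.DataFrame,
    pair_df: pd.DataFrame,
    age_bin_width: int,
) -> dict[str, pd.DataFrame]:
    subjects = set(pair_df["subject_id"]) if not pair_df.empty else set()
    demo = demographics[demographics["subject_id"].isin(subjects)].copy()
    orphans = subjects - set(demographics["subject_id"])
    if orphans:
        logger.warning(
            "demographics are missing %d subject(s) present in pairs: %s",
            len(orphans),
            sorted(orphans)[:10],
        )
    edges = list(range(0, 90 + age_bin_width, age_bin_width)) + [np.inf]
    labels = [
        f"{edges[i]}-{edges[i + 1] - 1}" for i in range(len(edges) - 2)
    ] + [f"{edges[-2]}+"]
    if demo.empty:
        age_hist = pd.DataFrame({"age_bin": labels, "count": 0})
    else:
        binned = pd.cut(demo["age"].astype(float), bins=edges, labels=labels, right=False)
        age_hist = binned.value_counts().reindex(labels, fill_value=0).rename_axis("age_bin").reset_index(name="count")
    gender = (
        demo.groupby("gender")["subject_id"].nunique().rename_axis("gender").reset_index(name="count")
        if not demo.empty
        else pd.DataFrame(columns=["gender", "count"])
    )
    ethnicity = (
        demo.groupby("ethnicity")["subject_id"].nunique().rename_axis("ethnicity").reset_index(name="count")
        if not demo.empty
        else pd.DataFrame(columns=["ethnicity", "count"])
    )
    return {"age_histogram": age_hist, "gender": gender, "ethnicity": ethnicity}


def save_report(bundle: ReportBundle, out_dir: str | Path) -> list[Path]:
    """Write one CSV per table; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "class_counts.csv": bundle.class_counts,
        "drug_counts.csv": bundle.drug_counts,
        "drug_ae_counts.csv": bundle.drug_ae_counts,
        "top_ae_per_drug.csv": bundle.top_ae_per_drug,
        "brand_generic_counts.csv": bundle.brand_generic_counts,
        "patient_lines.csv": bundle.patient_lines,
    }
    for name, table in tables.items():
        path = out / name
        table.to_csv(path, index=False)
        written.append(path)
    chord_path = out / "chord_matrix.csv"
    bundle.chord_matrix.to_csv(chord_path)
    written.append(chord_path)
    if bundle.demographics_summary:
        for name, table in bundle.demographics_summary.items():
            path = out / f"demographics_{name}.csv"
            table.to_csv(path, index=False)
            written.append(path)
    return written
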