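"""Individual-level responder matrices and the epitope catalog.

Detections from the barcode screen are aggregated to one row per
(individual, cohort class) — a patient's pre- and post-treatment samples are
distinct rows sharing the individual ID — over (peptide, HLA) columns with
tri-state cells: positive, negative, or not-tested (the individual lacks the
allele, so the pMHC never entered their staining pool).  Recognized epitopes
are classified as patient-only, healthy-donor-only, or shared, and per-HERV
reactivity scores summarize recognition relative to the tested library.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ResponderMatrix",
    "aggregate_responses",
    "classify_epitopes",
    "catalog_counts",
    "summarize_catalog",
    "reactivity_score",
    "epitope_proportion",
    "load_table1",
]

PATIENT_CLASSES = ("pre", "post")


@dataclass
class ResponderMatrix:
    """Tri-state recognition matrix: 1.0 positive, 0.0 negative, NaN not-tested.

    Rows are a MultiIndex (individual_id, class_); columns a MultiIndex
    (peptide, allele)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise ValueError("cells must be 1 (positive), 0 (negative), or NaN (not tested)")

    @property
    def classes(self) -> pd.Index:
        return self.values.index.get_level_values("class_")

    def patient_rows(self) -> pd.DataFrame:
        return self.values[self.classes.isin(PATIENT_CLASSES)]

    def healthy_rows(self) -> pd.DataFrame:
        return self.values[self.classes == "healthy"]

    def tested_denominators(self) -> pd.DataFrame:
        """Per-row count of tested (peptide, allele) columns, split by allele."""
        tested = self.values.notna()
        return tested.T.groupby(level="allele").sum().T

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.columns = [f"{p}|{a}" for p, a in out.columns]
        out.to_csv(path, sep="\t", na_rep="NA")


def _library_pairs(library) -> list[tuple[str, str]]:
    if isinstance(library, pd.DataFrame):
        return list(dict.fromkeys(zip(library["peptide"], library["allele"])))
    return list(dict.fromkeys((r.peptide, r.allele) for r in library))


def _peptide_loci(library) -> dict[str, frozenset[str]]:
    out: dict[str, frozenset[str]] = {}
    if isinstance(library, pd.DataFrame):
        for _, row in library.iterrows():
            loci = frozenset(s for s in str(row["source_loci"]).split(";") if s)
            out[row["peptide"]] = out.get(row["peptide"], frozenset()) | loci
    else:
        for rec in library:
            out[rec.peptide] = out.get(rec.peptide, frozenset()) | rec.source_loci
    return out


def _parse_alleles(cell: str) -> set[str]:
    return {a for a in str(cell).split(";") if a}


def aggregate_responses(
    detections: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    library,
) -> ResponderMatrix:
    """Aggregate per-sample detections to an individual x class matrix.

    A cell is positive when ANY of the individual's samples in that class has
    a significant detection for the (peptide, allele); tested cells are those
    whose allele the individual carries.  ``detections`` needs columns
    sample, peptide, allele (and optionally ``significant``, which is then
    used as a filter); every detection sample must appear in the sheet.
    """
    pairs = _library_pairs(library)
    sheet = sample_sheet.set_index("sample_id")
    rows = list(
        dict.fromkeys(zip(sheet["individual_id"], sheet["class_"]))
    )
    index = pd.MultiIndex.from_tuples(rows, names=["individual_id", "class_"])
    columns = pd.MultiIndex.from_tuples(pairs, names=["peptide", "allele"])
    values = pd.DataFrame(np.nan, index=index, columns=columns)

    alleles_by_ind = {
        ind: _parse_alleles(grp["alleles"].iloc[0])
        for ind, grp in sheet.groupby("individual_id")
    }
    for ind, cls in rows:
        carried = alleles_by_ind[ind]
        tested = [pair for pair in pairs if pair[1] in carried]
        values.loc[(ind, cls), tested] = 0.0

    det = detections
    if "significant" in det.columns:
        det = det[det["significant"].astype(bool)]
    for _, row in det.iterrows():
        sample = row["sample"]
        if sample not in sheet.index:
            raise ValueError(f"detection references unknown sample {sample!r}")
        ind = sheet.loc[sample, "individual_id"]
        cls = sheet.loc[sample, "class_"]
        pair = (row["peptide"], row["allele"])
        if pair in values.columns:
            values.loc[(ind, cls), pair] = 1.0
    return ResponderMatrix(values=values)


def classify_epitopes(
    matrix: ResponderMatrix,
    library=None,
) -> tuple[pd.DataFrame, tuple[int, int, int]]:
    """Label every recognized (peptide, allele) by cohort.

    Pre- and post-treatment rows both count as "patient".  Returns the
    catalog (peptide, allele, source_loci, cohort_label) and the counts
    (patient-only, healthy-only, shared)."""
    loci_map = _peptide_loci(library) if library is not None else {}
    pat = matrix.patient_rows()
    hd = matrix.healthy_rows()
    entries = []
    for pair in matrix.values.columns:
        in_pat = bool((pat[pair] == 1.0).any()) if len(pat) else False
        in_hd = bool((hd[pair] == 1.0).any()) if len(hd) else False
        if not (in_pat or in_hd):
            continue
        if in_pat and in_hd:
            label = "patient and healthy donor"
        elif in_pat:
            label = "patient"
        else:
            label = "healthy donor"
        entries.append(
            {
                "peptide": pair[0],
                "allele": pair[1],
                "source_loci": ";".join(sorted(loci_map.get(pair[0], frozenset()))),
                "cohort_label": label,
            }
        )
    catalog = pd.DataFrame(
        entries, columns=["peptide", "allele", "source_loci", "cohort_label"]
    )
    return catalog, catalog_counts(catalog)


def catalog_counts(catalog: pd.DataFrame) -> tuple[int, int, int]:
    """(patient-only, healthy-only, shared) entry counts of a catalog."""
    labels = catalog["cohort_label"]
    return (
        int((labels == "patient").sum()),
        int((labels == "healthy donor").sum()),
        int((labels == "patient and healthy donor").sum()),
    )


def summarize_catalog(catalog: pd.DataFrame) -> dict:
    """Per-allele entry counts, total entries, and distinct peptide count."""
    per_allele = catalog.groupby("allele").size().to_dict() if len(catalog) else {}
    return {
        "per_allele": per_allele,
        "total_entries": int(len(catalog)),
        "distinct_peptides": int(catalog["peptide"].nunique()) if len(catalog) else 0,
    }


def _locus_columns(matrix: ResponderMatrix, library) -> dict[str, list]:
    """Map each locus to the matrix columns whose peptide it encodes.
    Multi-locus peptides credit every source locus."""
    loci_map = _peptide_loci(library)
    out: dict[str, list] = {}
    for pair in matrix.values.columns:
        for locus in loci_map.get(pair[0], frozenset()):
            out.setdefault(locus, []).append(pair)
    return out


def reactivity_score(matrix: ResponderMatrix, library) -> pd.Series:
    """Per-HERV T cell reactivity score over patient rows.

    score(h) = (sum of positive peptide observations of h) /
    (sum of tested peptide observations of h), both summed across patient
    samples; loci never tested get NaN."""
    pat = matrix.patient_rows()
    scores = {}
    for locus, cols in _locus_columns(matrix, library).items():
        sub = pat[cols]
        tested = int(sub.notna().sum().sum())
        positive = int((sub == 1.0).sum().sum())
        scores[locus] = positive / tested if tested else np.nan
    return pd.Series(scores, name="reactivity_score").sort_index()


def epitope_proportion(matrix: ResponderMatrix, library) -> pd.Series:
    """Per-HERV proportion of predicted epitopes ever detected in a patient:
    distinct positive (peptide, allele) pairs / predicted pairs of the locus."""
    pat = matrix.patient_rows()
    out = {}
    for locus, cols in _locus_columns(matrix, library).items():
        detected = sum(bool((pat[c] == 1.0).any()) for c in cols)
        out[locus] = detected / len(cols)
    return pd.Series(out, name="epitope_proportion").sort_index()


def load_table1() -> pd.DataFrame:
    """The packaged catalog of the 29 HERV-derived T cell epitopes with their
    HLA restriction, source loci, and cohort annotation."""
    with resources.files("hervscreen.data").joinpath("table1_epitopes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
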