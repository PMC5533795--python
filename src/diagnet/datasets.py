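"""Expression dataset container: genes x samples matrix with clinical labels.

A cohort is stored as a pandas DataFrame of expression values (rows = gene
symbols, columns = sample identifiers) plus a sample-annotation table with the
tumor/normal group and the three immunohistochemistry receptor calls (ER, PR,
HER2) for tumor samples.  Gene symbols are upper-cased on construction so that
joins against interaction networks and gene-set libraries are case-stable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

#: the four clinically used receptor-based subtype classes
SUBTYPE_CLASSES = ("HR+HER2-", "HR+HER2+", "HR-HER2+", "TNG")

ANNOTATION_COLUMNS = ("sample", "group", "ER", "PR", "HER2")


def subtype_class(er: str, pr: str, her2: str) -> str:
    """Map receptor status calls ('+'/'-') to one of the four subtype classes.

    Hormone-receptor status follows ER when ER and PR disagree (discordant
    samples are assigned by ER).  TNG is the triple-negative group.
    """
    hr_positive = er == "+"
    if her2 == "+":
        return "HR+HER2+" if hr_positive else "HR-HER2+"
    return "HR+HER2-" if hr_positive else "TNG"


@dataclass
class ExpressionDataset:
    """One cohort: expression values plus per-sample annotations.

    Parameters
    ----------
    name : str
        Cohort identifier (e.g. a GEO accession or a synthetic cohort tag).
    values : DataFrame
        Genes (rows, upper-cased symbols) by samples (columns).
    annotations : DataFrame
        Indexed by sample id, columns ``group`` ('tumor'/'normal'), ``ER``,
        ``PR``, ``HER2`` ('+'/'-', or 'NA' for normals).
    """

    name: str
    values: pd.DataFrame
    annotations: pd.DataFrame
    discordant_samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.index = self.values.index.astype(str).str.upper()
        self.values.index.name = "gene"
        missing = set(self.values.columns) ^ set(self.annotations.index)
        if missing:
            raise ValueError(
                f"{self.name}: samples differ between matrix and annotations: "
                f"{sorted(missing)[:5]}"
            )
        self.annotations = self.annotations.loc[self.values.columns]
        tum = self.annotations[self.annotations["group"] == "tumor"]
        self.discordant_samples = list(tum.index[tum["ER"] != tum["PR"]])

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    @property
    def tumor_samples(self) -> list:
        return list(self.annotations.index[self.annotations["group"] == "tumor"])

    @property
    def normal_samples(self) -> list:
        return list(self.annotations.index[self.annotations["group"] == "normal"])

    def subtypes(self) -> pd.Series:
        """Four-class subtype label for every tumor sample."""
        tum = self.annotations.loc[self.tumor_samples]
        return pd.Series(
            [subtype_class(r.ER, r.PR, r.HER2) for r in tum.itertuples()],
            index=tum.index,
            name="subtype",
        )

    def group_matrices(self):
        """(tumor, normal) sub-matrices of the expression values."""
        return (
            self.values[self.tumor_samples],
            self.values[self.normal_samples],
        )


def write_dataset(dataset: ExpressionDataset, directory: str) -> dict:
    """Write a cohort as ``<name>.expr.tsv`` and ``<name>.annot.tsv``.

    Returns the mapping of logical names to the written paths.
    """
    os.makedirs(directory, exist_ok=True)
    expr_path = os.path.join(directory, f"{dataset.name}.expr.tsv")
    annot_path = os.path.join(directory, f"{dataset.name}.annot.tsv")
    dataset.values.to_csv(expr_path, sep="\t", index_label="gene", float_format="%.6g")
    annot = dataset.annotations.reset_index()
    annot.columns = list(ANNOTATION_COLUMNS)
    annot.to_csv(annot_path, sep="\t", index=False)
    return {"expression": expr_path, "annotations": annot_path}


def read_dataset(expr_path: str, annot_path: str, name: str | None = None) -> ExpressionDataset:
    """Read a cohort from the TSV pair produced by :func:`write_dataset`."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0).astype(float)
    annotations = pd.read_csv(annot_path, sep="\t", index_col=0, dtype=str)
    if name is None:
        name = os.path.basename(expr_path).split(".")[0]
    return ExpressionDataset(name=name, values=values, annotations=annotations)
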