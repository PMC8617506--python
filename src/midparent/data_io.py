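"""Domain types and TSV readers/writers for hybrid-panel expression studies.

All tables are tab-separated UTF-8 with a mandatory header row; ``NA`` (or an
empty cell in abundance tables) is the only missing-value marker.  Genotype
labels are case-sensitive opaque strings, so reciprocal hybrids such as
``B73xMo17`` and ``Mo17xB73`` are distinct entries.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

NA_MARKER = "NA"

ROLES = frozenset({"inbred", "hybrid", "mutant"})

#: Default controlled vocabulary for annotation group labels.  Labels outside
#: the vocabulary are retained under ``other`` so the enrichment universe never
#: shrinks silently.
DEFAULT_GROUP_VOCABULARY = frozenset({
    "PhANG",
    "PhAPG",
    "plastid_ribosome_NE",
    "plastid_ribosome_PE",
    "cytosolic_ribosome",
    "TPR",
    "carbon_fixation",
    "other",
})

DESIGN_COLUMNS = ("sample_id", "genotype", "replicate", "run", "tissue", "role")
CROSS_COLUMNS = ("hybrid", "parent_female", "parent_male")
TRAIT_COLUMNS = ("genotype", "height_cm")
ANNOTATION_COLUMNS = ("feature_id", "groups")


def _check_unique(values: pd.Index, what: str) -> None:
    dup = values[values.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate {what}(s): {', '.join(map(str, dup))}")


@dataclass
class AbundanceMatrix:
    """Nonnegative feature x sample quantities with explicit missing values.

    ``data`` is a float DataFrame indexed by feature id with one column per
    sample id; ``NaN`` marks a missing quantification (distinct from zero).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "feature id")
        _check_unique(df.columns, "sample id")
        df = df.astype(float)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = "feature_id"
        vals = df.to_numpy()
        neg = np.where(np.nan_to_num(vals, nan=0.0) < 0)
        if neg[0].size:
            r, c = neg[0][0], neg[1][0]
            raise ValueError(
                f"negative abundance at feature '{df.index[r]}', sample '{df.columns[c]}'"
            )
        self.data = df

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data[list(sample_ids)].copy())

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", na_rep=NA_MARKER, index_label="feature_id")


@dataclass
class SampleDesign:
    """Per-sample experimental metadata (genotype, replicate, run, tissue, role)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"design table missing column(s): {', '.join(missing)}")
        df = df[list(DESIGN_COLUMNS)]
        for col in ("sample_id", "genotype", "run", "tissue", "role"):
            df[col] = df[col].astype(str)
        _check_unique(pd.Index(df["sample_id"]), "sample id")
        df["replicate"] = df["replicate"].astype(int)
        bad_rep = df.loc[df["replicate"] < 1, "sample_id"]
        if len(bad_rep):
            raise ValueError(f"nonpositive replicate for sample '{bad_rep.iloc[0]}'")
        bad_role = df.loc[~df["role"].isin(ROLES), ["sample_id", "role"]]
        if len(bad_role):
            sid, role = bad_role.iloc[0]
            raise ValueError(
                f"unknown role '{role}' for sample '{sid}' (expected one of {sorted(ROLES)})"
            )
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.table["genotype"]))

    @property
    def runs(self) -> list[str]:
        return list(dict.fromkeys(self.table["run"]))

    def samples(
        self,
        genotype: str | None = None,
        tissue: str | None = None,
        run: str | None = None,
        role: str | None = None,
    ) -> pd.DataFrame:
        df = self.table
        for col, val in (
            ("genotype", genotype),
            ("tissue", tissue),
            ("run", run),
            ("role", role),
        ):
            if val is not None:
                df = df[df[col] == val]
        return df

    def check_matrix(self, matrix: AbundanceMatrix) -> None:
        """Every sample in the matrix must appear exactly once in the design."""
        known = set(self.table["sample_id"])
        unknown = [s for s in matrix.sample_ids if s not in known]
        if unknown:
            raise ValueError(f"sample(s) absent from design: {', '.join(unknown[:5])}")


@dataclass
class CrossPanel:
    """Hybrid -> (female parent, male parent) mapping; reciprocals are distinct rows."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in CROSS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cross table missing column(s): {', '.join(missing)}")
        df = df[list(CROSS_COLUMNS)].astype(str)
        _check_unique(pd.Index(df["hybrid"]), "hybrid label")
        same = df.loc[df["parent_female"] == df["parent_male"], "hybrid"]
        if len(same):
            raise ValueError(f"hybrid '{same.iloc[0]}' lists identical parents")
        self.table = df.reset_index(drop=True)

    @property
    def hybrids(self) -> list[str]:
        return list(self.table["hybrid"])

    def parents_of(self, hybrid: str) -> tuple[str, str]:
        row = self.table[self.table["hybrid"] == hybrid]
        if row.empty:
            raise KeyError(f"hybrid '{hybrid}' not in cross panel")
        return row["parent_female"].iloc[0], row["parent_male"].iloc[0]

    def check_design(self, design: SampleDesign) -> None:
        known = set(design.table["genotype"])
        for _, row in self.table.iterrows():
            for parent in (row["parent_female"], row["parent_male"]):
                if parent not in known:
                    raise ValueError(
                        f"parent '{parent}' of hybrid '{row['hybrid']}' absent from design"
                    )


@dataclass
class TraitTable:
    """Per-genotype trait values (plant height, cm, strictly positive)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trait table missing column(s): {', '.join(missing)}")
        df["genotype"] = df["genotype"].astype(str)
        df["height_cm"] = df["height_cm"].astype(float)
        _check_unique(pd.Index(df["genotype"]), "genotype")
        bad = df.loc[~(df["height_cm"] > 0), "genotype"]
        if len(bad):
            raise ValueError(f"nonpositive height for genotype '{bad.iloc[0]}'")
        self.table = df[list(df.columns)].reset_index(drop=True)

    def height(self, genotype: str) -> float:
        row = self.table[self.table["genotype"] == genotype]
        if row.empty:
            raise KeyError(f"genotype '{genotype}' not in trait table")
        return float(row["height_cm"].iloc[0])

    @property
    def heights(self) -> pd.Series:
        return self.table.set_index("genotype")["height_cm"]


@dataclass
class AnnotationTable:
    """Feature -> set of group labels drawn from a declared vocabulary.

    A feature may carry zero or many labels; labels outside ``vocabulary`` are
    mapped to ``other`` with a warning rather than dropped.
    """

    table: pd.DataFrame  # columns feature_id, groups (frozenset per row)
    vocabulary: frozenset = field(default=DEFAULT_GROUP_VOCABULARY)

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"annotation table missing column(s): {', '.join(missing)}")
        df["feature_id"] = df["feature_id"].astype(str)
        _check_unique(pd.Index(df["feature_id"]), "feature id")
        cleaned = []
        unknown: set[str] = set()
        for groups in df["groups"]:
            if isinstance(groups, str):
                labels = {g.strip() for g in groups.split(";") if g.strip()}
            else:
                labels = set(groups) if groups is not None else set()
            kept = set()
            for label in labels:
                if label in self.vocabulary:
                    kept.add(label)
                else:
                    unknown.add(label)
                    kept.add("other")
            cleaned.append(frozenset(kept))
        if unknown:
            warnings.warn(
                f"unknown annotation label(s) retained under 'other': {', '.join(sorted(unknown))}",
                stacklevel=2,
            )
        df["groups"] = cleaned
        self.table = df[list(ANNOTATION_COLUMNS)].reset_index(drop=True)

    @property
    def group_names(self) -> list[str]:
        names: set[str] = set()
        for groups in self.table["groups"]:
            names.update(groups)
        return sorted(names)

    def features_in(self, group: str) -> set[str]:
        mask = self.table["groups"].apply(lambda g: group in g)
        return set(self.table.loc[mask, "feature_id"])

    def groups_of(self, feature_id: str) -> frozenset:
        row = self.table[self.table["feature_id"] == feature_id]
        return row["groups"].iloc[0] if len(row) else frozenset()

    def groups_column(self, feature_ids: Iterable[str]) -> list[str]:
        """Semicolon-joined group labels per feature, '' for unannotated features."""
        lookup: Mapping[str, frozenset] = dict(
            zip(self.table["feature_id"], self.table["groups"])
        )
        return [";".join(sorted(lookup.get(f, frozenset()))) for f in feature_ids]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        keep_default_na=False,
        na_values=[NA_MARKER, ""],
        encoding="utf-8",
        **kwargs,
    )


def read_abundance_table(path: str | Path) -> AbundanceMatrix:
    """Read a feature x sample abundance TSV; empty cells and ``NA`` become missing."""
    df = _read_tsv(path, index_col=0, dtype_backend="numpy_nullable")
    df = df.astype(float)
    return AbundanceMatrix(df)


def read_design(path: str | Path) -> SampleDesign:
    return SampleDesign(_read_tsv(path))


def read_cross(path: str | Path) -> CrossPanel:
    return CrossPanel(_read_tsv(path))


def read_trait(path: str | Path) -> TraitTable:
    return TraitTable(_read_tsv(path))


def read_annotation(
    path: str | Path, vocabulary: frozenset = DEFAULT_GROUP_VOCABULARY
) -> AnnotationTable:
    df = _read_tsv(path)
    df["groups"] = df["groups"].fillna("")
    return AnnotationTable(df, vocabulary=vocabulary)


def write_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV (UTF-8, header row, missing rendered as ``NA``)."""
    df = table
    if "groups" in df.columns and len(df) and not isinstance(df["groups"].iloc[0], str):
        df = df.copy()
        df["groups"] = [";".join(sorted(g)) for g in df["groups"]]
    df.to_csv(path, sep="\t", na_rep=NA_MARKER, index=index, encoding="utf-8")


def write_abundance(matrix: AbundanceMatrix, path: str | Path) -> None:
    matrix.to_tsv(path)


def write_design(design: SampleDesign, path: str | Path) -> None:
    write_table(design.table, path)


def write_cross(panel: CrossPanel, path: str | Path) -> None:
    write_table(panel.table, path)


def write_trait(traits: TraitTable, path: str | Path) -> None:
    write_table(traits.table, path)


def write_annotation(annotation: AnnotationTable, path: str | Path) -> None:
    write_table(annotation.table, path)
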