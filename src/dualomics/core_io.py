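"""Data model and readers/writers for abundance, metabolite and metadata tables.

All tabular containers hold samples as rows internally; file readers transpose
the common taxa-as-rows dialects on the way in.  Abundance tables are
compositional: per-sample values sum (within tolerance) to a closure constant
of 1 or 100 and only ratio information is meaningful downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dualomics.errors import FormatError, ParameterError, ValidationError

# MetaPhlAn lineage prefixes, outermost to innermost rank.
_RANK_PREFIX = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
    "strain": "t__",
}

#: Default closure tolerance: per-sample sums may deviate from the closure
#: constant by this relative fraction before a table is rejected.
CLOSURE_TOL = 0.005


@dataclass
class AbundanceTable:
    """Samples x taxa relative-abundance matrix with per-sample closure.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with one column per taxon. Values are
        relative abundances on a common closure scale (fractions summing to 1
        or percentages summing to 100 per sample).
    closure:
        The closure constant (1.0 or 100.0).
    rank:
        Taxonomic rank of the columns, when known ("species", "genus", ...).
    """

    data: pd.DataFrame
    closure: float = 100.0
    rank: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ----------------------------------------------------

    def validate(self, tol: float = CLOSURE_TOL) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate taxon ids: {dupes}")
        vals = self.data.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValidationError("abundance table contains missing values")
        if (vals < 0).any():
            raise ValidationError("negative relative abundance")

    def check_closure(self, tol: float = CLOSURE_TOL) -> bool:
        """True when every sample sums to the closure constant within `tol`."""
        sums = self.data.sum(axis=1).to_numpy()
        return bool(np.all(np.abs(sums - self.closure) <= tol * self.closure))

    # -- convenience ---------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def renormalize(self) -> "AbundanceTable":
        """Re-close every sample exactly to the closure constant."""
        sums = self.data.sum(axis=1)
        if (sums <= 0).any():
            raise ValidationError("cannot renormalize a sample with zero total")
        data = self.data.div(sums, axis=0) * self.closure
        return AbundanceTable(data, closure=self.closure, rank=self.rank)

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(
            self.data.loc[list(sample_ids)], closure=self.closure, rank=self.rank
        )

    def subset_taxa(self, taxon_ids) -> "AbundanceTable":
        return AbundanceTable(
            self.data[list(taxon_ids)], closure=self.closure, rank=self.rank
        )


@dataclass
class MetaboliteTable:
    """Samples x annotated metabolites, plus metabolite -> pathway mapping.

    ``pathway_sizes`` carries the total compound count K_p of each pathway
    (measured or not); it is the denominator of pathway activity scores, so it
    must be at least the number of measured metabolites mapped to the pathway.
    """

    data: pd.DataFrame
    pathway_map: dict[str, set[str]] = field(default_factory=dict)
    pathway_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate sample ids in metabolite table")
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate metabolite ids")
        vals = self.data.to_numpy(dtype=float)
        if (vals[~np.isnan(vals)] < 0).any():
            raise ValidationError("negative metabolite abundance")
        measured = set(self.data.columns)
        mapped_counts: dict[str, int] = {}
        for met, paths in self.pathway_map.items():
            if met in measured:
                for p in paths:
                    mapped_counts[p] = mapped_counts.get(p, 0) + 1
        for p, k in mapped_counts.items():
            if p in self.pathway_sizes and self.pathway_sizes[p] < k:
                raise ValidationError(
                    f"pathway {p!r}: size {self.pathway_sizes[p]} < "
                    f"{k} measured metabolites mapped to it"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SampleMetadata:
    """Per-sample clinical table: group label plus glycemic / blood indices.

    Expected columns (all optional except ``group``): ``ogtt_glucose_0h``,
    ``ogtt_glucose_1h``, ``ogtt_glucose_2h``, ``fasting_insulin``, ``homa_ir``,
    ``hba1c``, ``bmi_prepregnancy``, ``neutrophil_count``, ``neutrophil_pct``,
    ``lymphocyte_pct``, ``tg``.  ``glucose_unit`` tags the OGTT columns with a
    single unit for the whole table ("mmol/L" or "mg/dL").
    """

    data: pd.DataFrame
    glucose_unit: str = "mmol/L"

    def __post_init__(self) -> None:
        if "group" not in self.data.columns:
            raise ValidationError("metadata must contain a 'group' column")
        if self.data["group"].isna().any():
            raise ValidationError("every sample needs a group label")
        if self.glucose_unit not in ("mmol/L", "mg/dL"):
            raise ValidationError(f"unknown glucose unit {self.glucose_unit!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    def subset_samples(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)], self.glucose_unit)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _infer_rank(clade: str) -> str | None:
    """Rank of a MetaPhlAn clade string, from its innermost lineage prefix."""
    last = clade.split("|")[-1]
    for rank, prefix in _RANK_PREFIX.items():
        if last.startswith(prefix):
            return rank
    return None


def _bare_name(clade: str) -> str:
    last = clade.split("|")[-1]
    for prefix in _RANK_PREFIX.values():
        if last.startswith(prefix):
            return last[len(prefix):]
    return last


def read_abundance_table(
    path: str | Path,
    rank: str | None = None,
    closure: float = 100.0,
    tol: float = CLOSURE_TOL,
    renormalize: bool = False,
) -> AbundanceTable:
    """Read a MetaPhlAn-style TSV (taxa as rows, samples as columns).

    Rows may carry full pipe-separated lineage strings (``k__...|s__X``) or
    bare taxon names.  When ``rank`` is given, lineage rows are filtered to
    that rank (bare-name rows are kept as-is, assumed pre-filtered).  Values
    are retained losslessly for the surviving rows.

    Raises
    ------
    FormatError
        Empty or header-less file.
    ValidationError
        Negative values, duplicate ids, or per-sample sums outside
        ``closure * (1 +/- tol)`` when ``renormalize`` is False.
    """
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")[1:]
                break
        else:
            raise FormatError(f"{path}: empty file")
    if len(header) != len(set(header)):
        raise ValidationError(f"{path}: duplicate sample columns")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")

    idx = df.index.astype(str)
    if rank is not None:
        if rank not in _RANK_PREFIX:
            raise ParameterError(f"unknown rank {rank!r}")
        has_lineage = idx.str.contains(r"\|") | idx.str.match(
            r"^[kpcofgst]__"
        )
        keep = np.array(
            [
                (_infer_rank(c) == rank) if lin else True
                for c, lin in zip(idx, has_lineage)
            ]
        )
        df = df.loc[keep]
    df.index = [_bare_name(str(c)) for c in df.index]
    if pd.Index(df.index).duplicated().any():
        raise ValidationError(f"{path}: duplicate taxon ids after rank filter")

    table = AbundanceTable(df.T.astype(float), closure=closure, rank=rank)
    if not table.check_closure(tol):
        if renormalize:
            table = table.renormalize()
        else:
            raise ValidationError(
                f"{path}: per-sample sums deviate from closure {closure} "
                f"by more than {tol:.1%} (pass renormalize=True to re-close)"
            )
    return table


def read_metabolite_table(
    path: str | Path,
    pathway_map_path: str | Path | None = None,
    pathway_sizes_path: str | Path | None = None,
) -> MetaboliteTable:
    """Read metabolites x samples TSV/CSV plus optional pathway mapping files.

    The pathway map is a 2-column TSV ``metabolite<TAB>pathway``; sizes are a
    2-column TSV ``pathway<TAB>total_compound_count``.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    pathway_map: dict[str, set[str]] = {}
    if pathway_map_path is not None:
        pm = pd.read_csv(pathway_map_path, sep="\t", header=0)
        if pm.shape[1] < 2:
            raise FormatError(f"{pathway_map_path}: need 2 columns")
        for met, pw in zip(pm.iloc[:, 0], pm.iloc[:, 1]):
            pathway_map.setdefault(str(met), set()).add(str(pw))
    pathway_sizes: dict[str, int] = {}
    if pathway_sizes_path is not None:
        ps = pd.read_csv(pathway_sizes_path, sep="\t", header=0)
        if ps.shape[1] < 2:
            raise FormatError(f"{pathway_sizes_path}: need 2 columns")
        pathway_sizes = {
            str(p): int(k) for p, k in zip(ps.iloc[:, 0], ps.iloc[:, 1])
        }
    return MetaboliteTable(df.T.astype(float), pathway_map, pathway_sizes)


def read_metadata(path: str | Path, glucose_unit: str = "mmol/L") -> SampleMetadata:
    """Read a clinical metadata CSV/TSV with sample ids in the first column."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return SampleMetadata(df, glucose_unit=glucose_unit)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def select_top_taxa(table: AbundanceTable, k: int) -> AbundanceTable:
    """Keep the ``k`` taxa with the highest mean relative abundance.

    Means are taken across all samples (groups pooled).  Ties at the rank-k
    boundary are broken lexicographically by taxon name so the selection is
    deterministic.  Sample order is preserved; retained values are unchanged.
    """
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    if k > table.n_taxa:
        raise ParameterError(f"k={k} exceeds {table.n_taxa} taxa")
    means = table.data.mean(axis=0)
    order = sorted(table.taxon_ids, key=lambda t: (-means[t], t))
    return table.subset_taxa(order[:k])


def collapse_to_genus(table: AbundanceTable, sep: str = " ") -> AbundanceTable:
    """Collapse species columns to genera by summation (no renormalization).

    The genus is the first whitespace/underscore-delimited token of the
    species name, matching MetaPhlAn ``Genus_species`` naming.
    """
    genera = [t.replace("_", " ").split(" ")[0] for t in table.taxon_ids]
    collapsed = table.data.T.groupby(pd.Index(genera, name="genus")).sum().T
    return AbundanceTable(collapsed, closure=table.closure, rank="genus")


def write_results(results: pd.DataFrame, path: str | Path) -> Path:
    """Write any result table as TSV (row index included when named).

    A round-trip through :func:`read_results` reproduces the frame within
    float tolerance.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    index = results.index.name is not None
    results.to_csv(path, sep="\t", index=index)
    return path


def read_results(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_manifest(path: str | Path, **entries) -> Path:
    """Write a JSON run manifest (parameters, seeds, row counts)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
    return path
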