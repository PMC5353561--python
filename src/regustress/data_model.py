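"""Typed containers and readers/writers for every file the pipeline touches.

All expression values are log2 scale throughout.  Identifiers are
case-sensitive strings; no symbol aliasing is performed.  Matrices may not
contain missing values.

File formats
------------
expression matrix
    Tab-delimited; header row of sample ids, first column of gene ids.
sample metadata
    Tab-delimited, keyed by sample id; columns ``condition`` (treatment |
    control | parent | evolved), ``replicate`` (int >= 1), ``strain``,
    ``time_h`` (int hours, may be empty), ``ethanol_pct`` (% v/v, may be
    empty).
gene sets
    GMT dialect: set name, category tag, then tab-separated gene ids.  An
    optional side table (set, gene, direction) carries per-gene tolerance
    direction annotations.
regulatory network
    Record-typed TSV: ``edge<TAB>TF<TAB>TU<TAB>sign`` rows,
    ``member<TAB>TU<TAB>gene`` rows and ``ebp<TAB>TF`` rows.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NS = "ns"
CALL_NOT_EXPRESSED = "not_expressed"
CALLS = (CALL_UP, CALL_DOWN, CALL_NS, CALL_NOT_EXPRESSED)

SIGN_ACTIVATION = "activation"
SIGN_REPRESSION = "repression"
SIGNS = (SIGN_ACTIVATION, SIGN_REPRESSION)

DIRECTION_OVEREXPRESSION = "overexpression_tolerant"
DIRECTION_KNOCKOUT = "knockout_tolerant"
DIRECTION_NONE = "none"
DIRECTIONS = (DIRECTION_OVEREXPRESSION, DIRECTION_KNOCKOUT, DIRECTION_NONE)

METADATA_COLUMNS = ("condition", "replicate", "strain", "time_h", "ethanol_pct")
CONDITIONS = ("treatment", "control", "parent", "evolved")


class ValidationError(ValueError):
    """An input violated a container invariant; the message names the offender."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionStudy:
    """A log2 genes x samples expression matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame of log2 expression, index = gene ids, columns = sample ids.
    metadata
        DataFrame indexed by sample id with columns ``condition``,
        ``replicate``, ``strain``, ``time_h``, ``ethanol_pct``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            bad = self.values.index[
                ~np.isfinite(self.values.to_numpy(dtype=float)).all(axis=1)
            ][0]
            raise ValidationError(f"non-finite expression value in gene {bad!r}")
        missing_meta = [s for s in self.values.columns if s not in self.metadata.index]
        if missing_meta:
            raise ValidationError(
                f"sample {missing_meta[0]!r} has no metadata record"
            )
        extra_meta = [s for s in self.metadata.index if s not in self.values.columns]
        if extra_meta:
            raise ValidationError(
                f"metadata sample {extra_meta[0]!r} missing from matrix"
            )
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ValidationError(f"metadata lacks required column {col!r}")
        for s, cond in self.metadata["condition"].items():
            if pd.isna(cond) or cond == "":
                raise ValidationError(f"sample {s!r} has no condition label")
            if cond not in CONDITIONS:
                raise ValidationError(
                    f"sample {s!r} has unknown condition {cond!r}"
                )

    def samples_where(self, **query: object) -> list[str]:
        """Sample ids whose metadata match all given column=value pairs."""
        mask = pd.Series(True, index=self.metadata.index)
        for col, val in query.items():
            mask &= self.metadata[col] == val
        return [s for s in self.values.columns if mask.get(s, False)]


@dataclass
class ContrastDesign:
    """One treatment-versus-control comparison."""

    name: str
    treatment: tuple[str, ...]
    control: tuple[str, ...]
    ethanol_pct: float | None = None

    def __post_init__(self) -> None:
        self.treatment = tuple(self.treatment)
        self.control = tuple(self.control)
        if not self.treatment or not self.control:
            raise ValidationError(f"contrast {self.name!r}: empty sample group")
        overlap = set(self.treatment) & set(self.control)
        if overlap:
            raise ValidationError(
                f"contrast {self.name!r}: sample {sorted(overlap)[0]!r} is in "
                "both treatment and control groups"
            )

    def validate_against(self, study: ExpressionStudy) -> None:
        known = set(study.samples)
        for s in (*self.treatment, *self.control):
            if s not in known:
                raise ValidationError(
                    f"contrast {self.name!r}: sample {s!r} not in study"
                )


class DEGTable:
    """Per-(gene, contrast) differential-expression calls.

    Wraps a DataFrame with columns ``gene``, ``contrast``, ``fold_change``
    (linear-scale ratio), ``p_value`` (NaN for the adaptive-evolution rule),
    ``mean_rel_diff`` (adaptive-evolution rule only) and ``call``.
    """

    COLUMNS = ("gene", "contrast", "fold_change", "p_value", "mean_rel_diff", "call")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"DEG table lacks column {missing[0]!r}")
        bad = set(frame["call"]) - set(CALLS)
        if bad:
            raise ValidationError(f"unknown DEG call {sorted(bad)[0]!r}")
        self.frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)

    @property
    def contrasts(self) -> list[str]:
        return list(dict.fromkeys(self.frame["contrast"]))

    def for_contrast(self, contrast: str) -> pd.DataFrame:
        sub = self.frame[self.frame["contrast"] == contrast]
        if sub.empty:
            raise KeyError(f"no DEG calls for contrast {contrast!r}")
        return sub

    def calls(self, contrast: str) -> pd.Series:
        """gene -> call for one contrast."""
        sub = self.for_contrast(contrast)
        return pd.Series(sub["call"].to_numpy(), index=sub["gene"].to_numpy())

    def genes_called(self, call: str, contrast: str | None = None) -> list[str]:
        sub = self.frame if contrast is None else self.for_contrast(contrast)
        return list(dict.fromkeys(sub.loc[sub["call"] == call, "gene"]))

    @staticmethod
    def concat(tables: Iterable["DEGTable"]) -> "DEGTable":
        return DEGTable(pd.concat([t.frame for t in tables], ignore_index=True))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DEGTable) and self.frame.equals(other.frame)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class GeneSet:
    name: str
    genes: tuple[str, ...]
    category: str | None = None
    directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        _check_unique(self.genes, f"gene (set {self.name!r})")
        for g, d in self.directions.items():
            if d not in DIRECTIONS:
                raise ValidationError(
                    f"set {self.name!r}: unknown direction {d!r} for gene {g!r}"
                )


class GeneSetCollection:
    """Named gene sets; sets may overlap, names are unique."""

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self.sets:
                raise ValidationError(f"duplicate gene-set name: {s.name!r}")
            self.sets[s.name] = s

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def by_category(self, category: str) -> list[GeneSet]:
        return [s for s in self if s.category == category]


@dataclass(frozen=True)
class RegEdge:
    tf: str
    tu: str
    sign: str

    def __post_init__(self) -> None:
        if not self.tf or not self.tu:
            raise ValidationError("network edge with empty TF or TU identifier")
        if self.sign not in SIGNS:
            raise ValidationError(
                f"unknown regulation sign {self.sign!r} on edge {self.tf}->{self.tu}"
            )


class RegulatoryNetwork:
    """Signed TF -> TU edges plus TU -> gene memberships.

    Every TU must have at least one member gene; duplicate edges are
    forbidden.  ``ebp_tfs`` flags transcription factors annotated as
    ethanol-binding proteins (an input annotation, not a prediction).
    """

    def __init__(
        self,
        edges: Iterable[RegEdge | tuple[str, str, str]],
        members: Mapping[str, Sequence[str]],
        ebp_tfs: Iterable[str] = (),
    ):
        self.edges: list[RegEdge] = []
        seen: set[tuple[str, str]] = set()
        for e in edges:
            if not isinstance(e, RegEdge):
                e = RegEdge(*e)
            key = (e.tf, e.tu)
            if key in seen:
                raise ValidationError(f"duplicate edge {e.tf}->{e.tu}")
            seen.add(key)
            self.edges.append(e)
        self.members: dict[str, tuple[str, ...]] = {
            tu: tuple(genes) for tu, genes in members.items()
        }
        for e in self.edges:
            if not self.members.get(e.tu):
                raise ValidationError(f"TU {e.tu!r} has no member genes")
        for tu, genes in self.members.items():
            if not genes:
                raise ValidationError(f"TU {tu!r} has no member genes")
            _check_unique(genes, f"member gene (TU {tu!r})")
        self.ebp_tfs = frozenset(ebp_tfs)

    @property
    def tfs(self) -> list[str]:
        return list(dict.fromkeys(e.tf for e in self.edges))

    @property
    def tus(self) -> list[str]:
        return list(self.members)

    def regulators_of(self, tu: str) -> list[str]:
        return [e.tf for e in self.edges if e.tu == tu]

    def edges_of(self, tf: str) -> list[RegEdge]:
        return [e for e in self.edges if e.tf == tf]

    def sole_regulator_tus(self, tf: str) -> list[RegEdge]:
        """Edges of ``tf`` to TUs for which ``tf`` is the only regulator."""
        counts: dict[str, int] = {}
        for e in self.edges:
            counts[e.tu] = counts.get(e.tu, 0) + 1
        return [e for e in self.edges if e.tf == tf and counts[e.tu] == 1]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, RegulatoryNetwork)
            and self.edges == other.edges
            and self.members == other.members
            and self.ebp_tfs == other.ebp_tfs
        )


@dataclass
class PipelineConfig:
    """Thresholds and method switches shared across pipeline stages.

    Defaults carry the published thresholds: fold change 1.2, alpha 0.05,
    20% mean relative difference for the adaptive-evolution rule.
    """

    fc_threshold: float = 1.2
    alpha: float = 0.05
    ea_min_mean_rel_diff: float = 0.20
    detection_threshold: float = 4.0
    rank_test: str = "ranksum_normal"  # ranksum_normal | ranksum_exact | signed_rank
    correlation_method: str = "pearson"  # pearson | spearman
    tu_rule: str = "majority"  # majority | any | all
    tie_tolerance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValidationError("fc_threshold must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.ea_min_mean_rel_diff <= 0:
            raise ValidationError("ea_min_mean_rel_diff must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key {sorted(unknown)[0]!r}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression_study(matrix_path: str | Path, metadata_path: str | Path) -> ExpressionStudy:
    """Read a tab-delimited log2 matrix plus its sample-metadata table."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype={0: str})
    meta.index = meta.index.astype(str)
    if "time_h" in meta.columns:
        meta["time_h"] = meta["time_h"].astype("Int64")
    if "replicate" in meta.columns:
        meta["replicate"] = meta["replicate"].astype(int)
    return ExpressionStudy(values=values, metadata=meta)


def write_expression_study(
    study: ExpressionStudy, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    study.values.to_csv(matrix_path, sep="\t", index_label="gene")
    study.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


def read_contrasts(path: str | Path) -> list[ContrastDesign]:
    df = pd.read_csv(path, sep="\t", dtype={"contrast": str, "sample": str, "role": str})
    out = []
    for name, sub in df.groupby("contrast", sort=False):
        eth = sub["ethanol_pct"].dropna()
        out.append(
            ContrastDesign(
                name=str(name),
                treatment=tuple(sub.loc[sub["role"] == "treatment", "sample"]),
                control=tuple(sub.loc[sub["role"] == "control", "sample"]),
                ethanol_pct=float(eth.iloc[0]) if len(eth) else None,
            )
        )
    return out


def write_contrasts(contrasts: Sequence[ContrastDesign], path: str | Path) -> None:
    rows = []
    for c in contrasts:
        for role, group in (("treatment", c.treatment), ("control", c.control)):
            for s in group:
                rows.append((c.name, s, role, c.ethanol_pct))
    pd.DataFrame(rows, columns=["contrast", "sample", "role", "ethanol_pct"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_sets(
    path: str | Path, directions_path: str | Path | None = None
) -> GeneSetCollection:
    """Read a GMT file; the second field is kept as the category tag.

    Empty sets are retained with a warning; malformed lines raise an error
    naming the line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(
                    f"{path}: malformed GMT line {lineno} (need name and category)"
                )
            name, category, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                warnings.warn(f"gene set {name!r} is empty; retained", stacklevel=2)
            sets.append(
                GeneSet(name=name, genes=tuple(genes), category=category or None)
            )
    coll = GeneSetCollection(sets)
    if directions_path is not None:
        side = pd.read_csv(directions_path, sep="\t", dtype=str)
        for _, row in side.iterrows():
            sname, gene, direction = row["set"], row["gene"], row["direction"]
            if sname not in coll.sets:
                raise ValidationError(f"direction table names unknown set {sname!r}")
            gs = coll.sets[sname]
            if gene not in gs.genes:
                raise ValidationError(
                    f"direction table: gene {gene!r} not in set {sname!r}"
                )
            if direction not in DIRECTIONS:
                raise ValidationError(f"unknown direction {direction!r}")
            gs.directions[gene] = direction
    return coll


def write_gene_sets(
    coll: GeneSetCollection,
    path: str | Path,
    directions_path: str | Path | None = None,
) -> None:
    with open(path, "w") as fh:
        for s in coll:
            fh.write("\t".join([s.name, s.category or "", *s.genes]) + "\n")
    if directions_path is not None:
        rows = [
            (s.name, g, d) for s in coll for g, d in sorted(s.directions.items())
        ]
        pd.DataFrame(rows, columns=["set", "gene", "direction"]).to_csv(
            directions_path, sep="\t", index=False
        )


def read_network(path: str | Path) -> RegulatoryNetwork:
    edges: list[RegEdge] = []
    members: dict[str, list[str]] = {}
    ebp: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "edge" and len(fields) == 4:
                edges.append(RegEdge(tf=fields[1], tu=fields[2], sign=fields[3]))
            elif kind == "member" and len(fields) == 3:
                members.setdefault(fields[1], []).append(fields[2])
            elif kind == "ebp" and len(fields) == 2:
                ebp.append(fields[1])
            else:
                raise ValidationError(f"{path}: malformed network line {lineno}")
    return RegulatoryNetwork(edges=edges, members=members, ebp_tfs=ebp)


def write_network(net: RegulatoryNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in net.edges:
            fh.write(f"edge\t{e.tf}\t{e.tu}\t{e.sign}\n")
        for tu, genes in net.members.items():
            for g in genes:
                fh.write(f"member\t{tu}\t{g}\n")
        for tf in sorted(net.ebp_tfs):
            fh.write(f"ebp\t{tf}\n")


def read_deg_table(path: str | Path) -> DEGTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "contrast": str, "call": str})
    return DEGTable(df)


def write_deg_table(table: DEGTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)
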