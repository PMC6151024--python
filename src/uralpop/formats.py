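"""Readers, writers and core domain containers for the pipeline.

All external formats are plain text: a native genotype TSV, the PLINK
transposed-text dialect (.tped/.tfam, read-only), IBD tract tables (native
TSV and a fastIBD-style indexed dialect), square CSV distance matrices,
CSV count tables (haplogroup counts, chunkcounts), Newick trees and YAML
configuration.

Conventions
-----------
* Genotypes are alt-allele dosages 0/1/2; missing is ``-1`` in memory and
  ``"NA"`` on disk.
* Male chrX genotypes are hemizygotes coded 0/2; a male chrX ``1`` is
  coerced to missing with a warning.
* Genetic-map coordinates are floats in cM; IBD intervals are half-open
  ``[start, end)`` so lengths add under merging.
* CSV is comma-separated, ``.`` decimal, UTF-8, header mandatory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

MISSING = -1

SEXES = {"male", "female", "unknown"}

SAMPLE_COLUMNS = ["sample_id", "population", "sex", "language_group",
                  "region", "lat", "lon"]

IBD_COLUMNS = ["sample_a", "sample_b", "chrom", "start_cm", "end_cm",
               "score", "run_id"]


class ParseError(ValueError):
    """Malformed input that could not be tokenised as the declared format."""


class FormatError(ValueError):
    """Structurally well-formed input that violates the format contract."""


class ValidationError(ValueError):
    """Input that parses but violates a domain invariant."""


def is_uralic(language_group: str) -> bool:
    """A language-group label counts as Uralic when its family field is Uralic.

    Labels are ``Family`` or ``Family:Branch`` (e.g. ``Uralic:Finnic``).
    """
    return language_group.split(":")[0].strip().lower() == "uralic"


# ---------------------------------------------------------------------------
# GenotypeDataset
# ---------------------------------------------------------------------------

@dataclass
class GenotypeDataset:
    """SNP x sample alt-allele dosage matrix with map positions.

    ``calls`` holds integers in {0, 1, 2} with ``-1`` for missing.
    Autosomes are labelled "1".."22"; the X chromosome is "X".  Male chrX
    hemizygotes are coded 0/2.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    pos_cm: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    samples: list[str]
    calls: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in ids], dtype=int)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            snp_ids=self.snp_ids[mask], chrom=self.chrom[mask],
            pos_bp=self.pos_bp[mask], pos_cm=self.pos_cm[mask],
            ref=self.ref[mask], alt=self.alt[mask],
            samples=list(self.samples), calls=self.calls[mask],
        )

    def validate(self, sex: Mapping[str, str] | None = None) -> None:
        """Check all container invariants; raise ValidationError on failure."""
        n_snps, n_samples = self.calls.shape
        if n_snps != self.n_snps or n_samples != self.n_samples:
            raise ValidationError("calls shape does not match snp/sample counts")
        if len(set(self.snp_ids)) != self.n_snps:
            raise ValidationError("duplicate SNP ids")
        if len(set(self.samples)) != self.n_samples:
            raise ValidationError("duplicate sample ids")
        ok = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValidationError(
                f"invalid call {self.calls[tuple(bad)]} at SNP row {bad[0]}")
        if (self.pos_bp < 1).any():
            raise ValidationError("pos_bp must be >= 1")
        if (self.pos_cm < 0).any():
            raise ValidationError("pos_cm must be non-negative")
        for c in pd.unique(self.chrom):
            idx = np.flatnonzero(self.chrom == c)
            if (np.diff(self.pos_bp[idx]) < 0).any():
                raise ValidationError(f"pos_bp not sorted within chromosome {c}")
            if (np.diff(self.pos_cm[idx]) < 0).any():
                raise ValidationError(f"pos_cm not sorted within chromosome {c}")
        if sex is not None:
            x = self.chrom == "X"
            if x.any():
                males = [i for i, s in enumerate(self.samples)
                         if sex.get(s) == "male"]
                if males:
                    mx = self.calls[np.ix_(x, males)]
                    if (mx == 1).any():
                        raise ValidationError(
                            "male chrX heterozygote call present")


def _sex_lookup(samples: pd.DataFrame | None) -> dict[str, str]:
    if samples is None:
        return {}
    return dict(zip(samples["sample_id"], samples["sex"]))


def _coerce_male_chrx_hets(g: GenotypeDataset, sex: Mapping[str, str]) -> None:
    """Force male chrX heterozygote calls to missing, warning once."""
    if not sex:
        return
    x = g.chrom == "X"
    if not x.any():
        return
    males = [i for i, s in enumerate(g.samples) if sex.get(s) == "male"]
    if not males:
        return
    sub = g.calls[np.ix_(x, males)]
    n_het = int((sub == 1).sum())
    if n_het:
        sub[sub == 1] = MISSING
        g.calls[np.ix_(x, males)] = sub
        warnings.warn(f"coerced {n_het} male chrX heterozygote call(s) to missing")


def read_genotypes(path: str | Path, dialect: str = "native_tsv",
                   samples: pd.DataFrame | None = None) -> GenotypeDataset:
    """Read a genotype matrix from the native TSV or PLINK .tped dialect.

    For ``plink_tped`` a companion ``.tfam`` file must sit next to the
    ``.tped``; the counted (alt) allele of each SNP is the first allele
    encountered on its row, and ``0 0`` pairs are missing.  If ``samples``
    (a sample table) is given, male chrX heterozygotes are coerced to
    missing with a warning.
    """
    path = Path(path)
    if dialect == "native_tsv":
        g = _read_native_tsv(path)
    elif dialect == "plink_tped":
        g = _read_plink_tped(path)
    else:
        raise ValueError(f"unknown genotype dialect: {dialect!r}")
    _coerce_male_chrx_hets(g, _sex_lookup(samples))
    g.validate(sex=_sex_lookup(samples) or None)
    return g


def _read_native_tsv(path: Path) -> GenotypeDataset:
    meta_cols = ["snp_id", "chrom", "pos_bp", "pos_cm", "ref", "alt"]
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:6] != meta_cols:
            raise FormatError(
                f"native genotype TSV must start with columns {meta_cols}")
        sample_ids = header[6:]
        n = len(sample_ids)
        if len(set(sample_ids)) != n:
            raise FormatError("duplicate sample ids in header")
        rows, seen = [], set()
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6 + n:
                raise ParseError(f"line {lineno}: expected {6 + n} fields, "
                                 f"got {len(parts)}")
            if parts[0] in seen:
                raise FormatError(f"line {lineno}: duplicate SNP id {parts[0]}")
            seen.add(parts[0])
            try:
                calls = [MISSING if v == "NA" else int(v) for v in parts[6:]]
                rows.append((parts[0], parts[1], int(parts[2]),
                             float(parts[3]), parts[4], parts[5], calls))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
    return GenotypeDataset(
        snp_ids=np.array([r[0] for r in rows]),
        chrom=np.array([r[1] for r in rows]),
        pos_bp=np.array([r[2] for r in rows], dtype=np.int64),
        pos_cm=np.array([r[3] for r in rows], dtype=float),
        ref=np.array([r[4] for r in rows]),
        alt=np.array([r[5] for r in rows]),
        samples=sample_ids,
        calls=np.array([r[6] for r in rows], dtype=np.int8).reshape(len(rows), n),
    )


def write_genotypes(g: GenotypeDataset, path: str | Path) -> None:
    """Write the native genotype TSV (round-trips with read_genotypes)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["snp_id", "chrom", "pos_bp", "pos_cm",
                            "ref", "alt"] + list(g.samples)) + "\n")
        for i in range(g.n_snps):
            calls = ["NA" if c == MISSING else str(int(c)) for c in g.calls[i]]
            fh.write("\t".join([g.snp_ids[i], g.chrom[i], str(int(g.pos_bp[i])),
                                repr(float(g.pos_cm[i])), g.ref[i], g.alt[i]]
                               + calls) + "\n")


def _read_plink_tped(path: Path) -> GenotypeDataset:
    tfam = path.with_suffix(".tfam")
    if not tfam.exists():
        raise FormatError(f"companion .tfam not found next to {path}")
    fam = pd.read_csv(tfam, sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype=str)
    sample_ids = list(fam["iid"])
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError("duplicate sample ids in .tfam")
    n = len(sample_ids)
    rows, seen = [], set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4 + 2 * n:
                raise ParseError(f"line {lineno}: expected {4 + 2 * n} fields, "
                                 f"got {len(parts)}")
            chrom, snp_id, cm, bp = parts[:4]
            if chrom == "23":
                chrom = "X"
            if snp_id in seen:
                raise FormatError(f"line {lineno}: duplicate SNP id {snp_id}")
            seen.add(snp_id)
            pairs = list(zip(parts[4::2], parts[5::2]))
            alleles: list[str] = []
            for a, b in pairs:
                for al in (a, b):
                    if al != "0" and al not in alleles:
                        alleles.append(al)
            if len(alleles) > 2:
                raise ParseError(
                    f"line {lineno}: more than two alleles at {snp_id}")
            # counted (alt) allele = first allele observed on the row
            alt = alleles[0] if alleles else "0"
            ref = alleles[1] if len(alleles) > 1 else "0"
            calls = []
            for a, b in pairs:
                if a == "0" or b == "0":
                    calls.append(MISSING)
                else:
                    calls.append(int(a == alt) + int(b == alt))
            try:
                rows.append((snp_id, chrom, int(bp), float(cm), ref, alt, calls))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
    return GenotypeDataset(
        snp_ids=np.array([r[0] for r in rows]),
        chrom=np.array([r[1] for r in rows]),
        pos_bp=np.array([r[2] for r in rows], dtype=np.int64),
        pos_cm=np.array([r[3] for r in rows], dtype=float),
        ref=np.array([r[4] for r in rows]),
        alt=np.array([r[5] for r in rows]),
        samples=sample_ids,
        calls=np.array([r[6] for r in rows], dtype=np.int8).reshape(len(rows), n),
    )


# ---------------------------------------------------------------------------
# Sample table
# ---------------------------------------------------------------------------

def read_samples(path: str | Path) -> pd.DataFrame:
    """Read a sample table TSV with the canonical column set."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str,
                                            "sex": str, "language_group": str,
                                            "region": str})
    validate_samples(df)
    return df


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def validate_samples(df: pd.DataFrame,
                     genotype_samples: Sequence[str] | None = None,
                     regions: set[str] | None = None) -> None:
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"sample table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample id {dup!r}")
    bad_sex = set(df["sex"]) - SEXES
    if bad_sex:
        raise ValidationError(f"invalid sex value(s): {sorted(bad_sex)}")
    if ((df["lat"] < -90) | (df["lat"] > 90)).any():
        raise ValidationError("latitude outside [-90, 90]")
    if ((df["lon"] < -180) | (df["lon"] > 180)).any():
        raise ValidationError("longitude outside [-180, 180]")
    if genotype_samples is not None:
        got = set(df["sample_id"])
        absent = set(genotype_samples) - got
        if absent:
            raise ValidationError(
                f"genotype samples missing from sample table: {sorted(absent)[:5]}")
    if regions is not None:
        bad = set(df["region"]) - regions
        if bad:
            raise ValidationError(f"undeclared region(s): {sorted(bad)}")


# ---------------------------------------------------------------------------
# IBD tracts
# ---------------------------------------------------------------------------

def canonicalize_tracts(df: pd.DataFrame) -> pd.DataFrame:
    """Order each pair lexicographically (sample_a < sample_b)."""
    df = df.copy()
    swap = df["sample_a"] > df["sample_b"]
    a = df.loc[swap, "sample_a"].copy()
    df.loc[swap, "sample_a"] = df.loc[swap, "sample_b"]
    df.loc[swap, "sample_b"] = a
    return df


def validate_tracts(df: pd.DataFrame) -> None:
    missing = set(IBD_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"tract table missing columns: {sorted(missing)}")
    if (df["start_cm"] >= df["end_cm"]).any():
        raise ValidationError("tract with start_cm >= end_cm")
    if (df["sample_a"] == df["sample_b"]).any():
        raise ValidationError("self-pair tract")
    if (df["score"] <= 0).any():
        raise ValidationError("non-positive fastIBD score")


def read_ibd_tracts(path: str | Path, dialect: str = "native_tsv",
                    marker_map: np.ndarray | Sequence[float] | None = None,
                    chrom: str | None = None, run_id: int = 1,
                    columns: Sequence[str] = ("sample_a", "sample_b",
                                              "start_idx", "end_idx", "score"),
                    ) -> pd.DataFrame:
    """Read IBD tracts; returns a canonicalized DataFrame with IBD_COLUMNS.

    ``native_tsv`` carries cM intervals directly.  ``fastibd_like`` rows carry
    marker *indices* into ``marker_map`` (the per-chromosome cM positions of
    the markers the detector saw); the column order of the headerless file is
    configurable via ``columns`` since detectors differ.  Degenerate records
    (end <= start after conversion) are dropped; the count of dropped rows is
    stored in ``df.attrs["n_rejected"]`` and reported as a warning.
    """
    path = Path(path)
    if dialect == "native_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"sample_a": str, "sample_b": str,
                                                "chrom": str})
        missing = set(IBD_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"tract table missing columns: {sorted(missing)}")
    elif dialect == "fastibd_like":
        if marker_map is None or chrom is None:
            raise ValueError("fastibd_like dialect requires marker_map and chrom")
        marker_map = np.asarray(marker_map, dtype=float)
        raw = pd.read_csv(path, sep=r"\s+", header=None, names=list(columns),
                          dtype={"sample_a": str, "sample_b": str})
        for col in ("start_idx", "end_idx"):
            idx = raw[col].to_numpy()
            if (idx < 0).any() or (idx >= len(marker_map)).any():
                bad = raw.index[(idx < 0) | (idx >= len(marker_map))][0]
                raise ParseError(
                    f"row {bad}: marker index outside map of length {len(marker_map)}")
        df = pd.DataFrame({
            "sample_a": raw["sample_a"],
            "sample_b": raw["sample_b"],
            "chrom": chrom,
            "start_cm": marker_map[raw["start_idx"].to_numpy()],
            "end_cm": marker_map[raw["end_idx"].to_numpy()],
            "score": raw["score"].astype(float),
            "run_id": run_id,
        })
    else:
        raise ValueError(f"unknown IBD dialect: {dialect!r}")

    degenerate = df["start_cm"] >= df["end_cm"]
    n_rejected = int(degenerate.sum())
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} degenerate IBD record(s)")
        df = df[~degenerate]
    df = canonicalize_tracts(df.reset_index(drop=True))
    validate_tracts(df)
    df.attrs["n_rejected"] = n_rejected
    return df


def write_ibd_tracts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=IBD_COLUMNS)


# ---------------------------------------------------------------------------
# DistanceMatrix
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Labelled symmetric non-negative matrix with zero diagonal.

    NaN cells mark pairs for which the underlying statistic is undefined
    (e.g. an infinite linearized Phi_ST); downstream consumers drop the
    affected labels complete-case.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(self.values - self.values.T), initial=0.0)
        if asym > 1e-9 or (np.isnan(self.values) != np.isnan(self.values.T)).any():
            raise ValidationError(f"matrix asymmetric (max |d - d.T| = {asym:g})")
        if np.nanmax(np.abs(np.diag(self.values)), initial=0.0) > 1e-9:
            raise ValidationError("non-zero diagonal entry")
        off = self.values[~np.eye(n, dtype=bool)]
        if np.nanmin(off, initial=0.0) < 0:
            raise ValidationError("negative distance entry")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def missing_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if np.isnan(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        if set(labels) != set(self.labels) or len(labels) != self.n:
            raise ValueError("reorder requires the same label set")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries (row-major, i > j)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def read_square_matrix(path: str | Path) -> DistanceMatrix:
    """Read a labelled square CSV matrix, symmetrizing tiny asymmetries.

    Asymmetries below 1e-6 (e.g. printing round-off) are averaged away;
    anything larger is a validation error.
    """
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"matrix is {df.shape[0]}x{df.shape[1]}, not square")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise FormatError("row labels do not match column labels")
    vals = df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        asym = np.nanmax(np.abs(vals - vals.T), initial=0.0)
    if asym >= 1e-6:
        raise ValidationError(f"matrix asymmetry {asym:g} >= 1e-6")
    vals = (vals + vals.T) / 2.0
    return DistanceMatrix(list(df.index.astype(str)), vals)


def write_square_matrix(m: DistanceMatrix, path: str | Path) -> None:
    m.to_dataframe().to_csv(path, float_format="%.17g")


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

@dataclass
class HaplogroupTable:
    """Population x haplogroup count table for one uniparental locus."""

    locus: str  # "mtDNA" or "chrY"
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.locus not in ("mtDNA", "chrY"):
            raise ValidationError(f"unknown locus {self.locus!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative haplogroup count")

    def frequencies(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            zero = totals.index[totals == 0][0]
            raise ValidationError(f"population {zero!r} has zero total count")
        return self.counts.div(totals, axis=0)


@dataclass
class ChunkcountMatrix:
    """Recipient x donor copying-count matrix (fineSTRUCTURE-style)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative chunkcount")
        if (self.counts.sum(axis=1) <= 0).any():
            bad = self.counts.index[self.counts.sum(axis=1) <= 0][0]
            raise ValidationError(f"recipient {bad!r} has non-positive row sum")

    @property
    def self_copy_donors(self) -> list[str]:
        """Donor columns that name a recipient (self-copy cells to ignore)."""
        return [d for d in self.counts.columns if d in set(self.counts.index)]


def read_counts_table(path: str | Path, kind: str, locus: str = "chrY"):
    """Read a haplogroup count table or chunkcount matrix from CSV."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    vals = df.to_numpy()
    if (vals < 0).any():
        i, j = np.argwhere(vals < 0)[0]
        raise ValidationError(
            f"negative entry at row {df.index[i]!r}, column {df.columns[j]!r}")
    if kind == "haplogroup":
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("haplogroup counts must be integers")
        return HaplogroupTable(locus=locus, counts=df.round().astype(int))
    if kind == "chunkcount":
        return ChunkcountMatrix(counts=df.astype(float))
    raise ValueError(f"unknown counts kind: {kind!r}")


def write_counts_table(table, path: str | Path) -> None:
    table.counts.to_csv(path)


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree; every non-root edge needs a length >= 0."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises assorted error classes
        raise ParseError(f"could not parse Newick file {path}: {exc}") from None
    validate_tree(tree)
    return tree


def validate_tree(tree: dendropy.Tree) -> None:
    labels = [t.label for t in tree.taxon_namespace]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate tip labels")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValidationError("edge without branch length "
                                  "(lengths required for patristic distances)")
        if edge.length < 0:
            raise ValidationError(f"negative branch length {edge.length}")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, real_value_format_specifier=".12g")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("configuration must be a mapping at top level")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
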