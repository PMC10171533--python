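"""GWAS summary-statistics and LD-score I/O, harmonisation and QC.

Every downstream estimator in this package consumes :class:`SumStatsTable`
and :class:`LdScoreTable` objects produced here.  Tables are thin wrappers
around a :class:`pandas.DataFrame` with a fixed column layout::

    snp  chrom  bp  a1  a2  eaf  beta  se  z  n

where ``a1`` is the effect allele, ``eaf`` its frequency, ``beta``/``se``
the additive effect and standard error on a standardised trait, ``z`` the
signed association statistic and ``n`` the per-variant sample size.

The on-disk dialect is whitespace/tab-delimited text with an LDSC-style
header (``SNP CHR BP A1 A2 EAF BETA SE Z N``); gzip is handled
transparently by pandas.  LD scores are ``SNP  L2`` plus a one-integer
sidecar ``<path>.M`` file holding M, the number of SNPs the heritability
is scaled to.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError, InputError

log = logging.getLogger(__name__)

#: canonical internal column order
COLUMNS = ["snp", "chrom", "bp", "a1", "a2", "eaf", "beta", "se", "z", "n"]

#: default file-header names for each internal column
DEFAULT_HEADER = {
    "snp": "SNP", "chrom": "CHR", "bp": "BP", "a1": "A1", "a2": "A2",
    "eaf": "EAF", "beta": "BETA", "se": "SE", "z": "Z", "n": "N",
}

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SumStatsTable:
    """One trait's per-variant GWAS results in a harmonised allele frame."""

    trait_label: str
    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise InputError(f"sumstats frame missing columns {missing}")
        self.df = self.df.loc[:, COLUMNS].reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.df["snp"].to_numpy()

    def copy(self) -> "SumStatsTable":
        return SumStatsTable(self.trait_label, self.df.copy())

    def validate(self) -> None:
        """Raise :class:`InputError` on any violated table invariant."""
        df = self.df
        if df["snp"].duplicated().any():
            raise InputError(f"{self.trait_label}: duplicate variant ids")
        if (df["a1"] == df["a2"]).any():
            raise InputError(f"{self.trait_label}: a1 == a2 for some variants")
        if not ((df["eaf"] > 0) & (df["eaf"] < 1)).all():
            raise InputError(f"{self.trait_label}: eaf outside (0,1)")
        if (df["n"] < 1).any():
            raise InputError(f"{self.trait_label}: sample size < 1")
        both = df["beta"].notna() & df["se"].notna()
        if both.any():
            z = df.loc[both, "z"]
            ratio = df.loc[both, "beta"] / df.loc[both, "se"]
            tol = 1e-6 * np.maximum(1.0, np.abs(z))
            if (np.abs(z - ratio) > tol).any():
                raise InputError(f"{self.trait_label}: z inconsistent with beta/se")


@dataclass
class LdScoreTable:
    """LD scores ℓ_j and the SNP count M used for heritability scaling."""

    df: pd.DataFrame  # columns: snp, l2
    m_total: int

    def __post_init__(self):
        if not {"snp", "l2"}.issubset(self.df.columns):
            raise InputError("LD score frame needs columns snp, l2")
        if self.df["snp"].duplicated().any():
            raise InputError("duplicate variant ids in LD score table")
        if not np.isfinite(self.df["l2"]).all():
            raise InputError("non-finite LD scores")
        self.df = self.df.loc[:, ["snp", "l2"]].reset_index(drop=True)


@dataclass
class HarmonizeReport:
    """Bookkeeping for :func:`harmonize`, counted on the reference frame."""

    n_kept: int = 0
    n_flipped: int = 0
    n_strand_dropped: int = 0
    n_missing_dropped: int = 0


def read_sumstats(path, trait_label: str | None = None,
                  column_map: Mapping[str, str] | None = None) -> SumStatsTable:
    """Read a GWAS summary-statistics file.

    Parameters
    ----------
    path:
        Delimited text file (optionally gzipped) with a header row.
    trait_label:
        Label for the trait; defaults to the file stem.
    column_map:
        Optional mapping from internal column names (``snp``, ``chrom``,
        ``bp``, ``a1``, ``a2``, ``eaf``, ``beta``, ``se``, ``z``, ``n``) to
        the header names used in the file.  Unmapped columns fall back to
        the LDSC-style defaults (``SNP``, ``CHR``, ...).

    Rows with non-ACGT alleles, identical alleles, frequencies outside
    (0,1) or missing mandatory fields are dropped with a logged count.
    ``z`` is back-filled as ``beta/se`` where absent.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"sumstats file not found: {path}")
    raw = pd.read_csv(path, sep=r"\s+")
    cmap = dict(DEFAULT_HEADER)
    if column_map:
        cmap.update(column_map)
    # case-insensitive header resolution
    lower = {c.lower(): c for c in raw.columns}
    resolved = {}
    for internal, header in cmap.items():
        if header in raw.columns:
            resolved[internal] = header
        elif header.lower() in lower:
            resolved[internal] = lower[header.lower()]

    mandatory = ["snp", "chrom", "bp", "a1", "a2", "eaf", "n"]
    missing = [c for c in mandatory if c not in resolved]
    if missing:
        raise ConfigurationError(
            f"{path}: cannot resolve mandatory columns {missing} "
            f"(header: {list(raw.columns)})")
    has_beta = "beta" in resolved and "se" in resolved
    has_z = "z" in resolved
    if not (has_beta or has_z):
        raise ConfigurationError(
            f"{path}: need either BETA+SE or Z column")

    df = pd.DataFrame({c: raw[resolved[c]] for c in resolved})
    for c in ("beta", "se", "z"):
        if c not in df.columns:
            df[c] = np.nan
    n_in = len(df)

    df["a1"] = df["a1"].astype(str).str.upper()
    df["a2"] = df["a2"].astype(str).str.upper()
    ok = (df["a1"].isin(_VALID_ALLELES) & df["a2"].isin(_VALID_ALLELES)
          & (df["a1"] != df["a2"]))
    ok &= df["eaf"].notna() & (df["eaf"] > 0) & (df["eaf"] < 1)
    ok &= df["snp"].notna() & df["n"].notna() & (df["n"] >= 1)
    if has_beta:
        stat_ok = df["beta"].notna() & df["se"].notna() & (df["se"] > 0)
        if has_z:
            stat_ok |= df["z"].notna()
    else:
        stat_ok = df["z"].notna()
    ok &= stat_ok
    ok &= ~df["snp"].duplicated(keep="first")
    df = df.loc[ok].reset_index(drop=True)
    n_dropped = n_in - len(df)
    if n_dropped:
        log.info("%s: dropped %d of %d rows failing validation",
                 path.name, n_dropped, n_in)
    if df.empty:
        raise EmptyInputError(f"{path}: no valid rows after filtering")

    fill = df["z"].isna() & df["beta"].notna() & df["se"].notna()
    df.loc[fill, "z"] = df.loc[fill, "beta"] / df.loc[fill, "se"]

    df["bp"] = df["bp"].astype(np.int64)
    df["chrom"] = df["chrom"].astype(str)
    table = SumStatsTable(trait_label or path.stem.split(".")[0], df)
    table.validate()
    return table


def write_sumstats(table: SumStatsTable, path, header_lines: Sequence[str] = ()) -> None:
    """Write a table in the default dialect (12 significant digits)."""
    path = Path(path)
    out = table.df.rename(columns=DEFAULT_HEADER)
    with pd.io.common.get_handle(path, "w", compression="infer") as handles:
        for line in header_lines:
            handles.handle.write(f"# {line}\n")
        out.to_csv(handles.handle, sep="\t", index=False, float_format="%.12g")


def read_ldscores(path, m_path=None) -> LdScoreTable:
    """Read ``SNP  L2`` LD scores plus the one-integer M sidecar file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"LD score file not found: {path}")
    raw = pd.read_csv(path, sep=r"\s+", comment="#")
    lower = {c.lower(): c for c in raw.columns}
    try:
        df = pd.DataFrame({"snp": raw[lower["snp"]], "l2": raw[lower["l2"]]})
    except KeyError as exc:
        raise ConfigurationError(f"{path}: need SNP and L2 columns") from exc
    m_path = Path(m_path) if m_path is not None else Path(str(path) + ".M")
    if not m_path.exists():
        raise ConfigurationError(f"M sidecar file not found: {m_path}")
    m_total = int(float(m_path.read_text().split()[0]))
    return LdScoreTable(df, m_total)


def write_ldscores(ld: LdScoreTable, path, m_path=None) -> None:
    path = Path(path)
    out = ld.df.rename(columns={"snp": "SNP", "l2": "L2"})
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")
    m_path = Path(m_path) if m_path is not None else Path(str(path) + ".M")
    m_path.write_text(f"{ld.m_total}\n")


def _orient(df: pd.DataFrame, ref: pd.DataFrame, policy: str):
    """Classify each merged row: 0 keep, 1 flip, -1 strand-drop, -2 irreconcilable.

    ``df`` must already be merged with the reference allele columns
    ``ra1``/``ra2``/``reaf``.  Complement-strand encodings are folded onto
    the reference strand before comparison.
    """
    a1, a2 = df["a1"].to_numpy(), df["a2"].to_numpy()
    ra1, ra2 = df["ra1"].to_numpy(), df["ra2"].to_numpy()
    ca1 = np.array([_COMPLEMENT[a] for a in a1])
    ca2 = np.array([_COMPLEMENT[a] for a in a2])

    pal = np.array([(x, y) in _PALINDROMIC for x, y in zip(a1, a2)])
    same = (a1 == ra1) & (a2 == ra2)
    flip = (a1 == ra2) & (a2 == ra1)
    csame = (ca1 == ra1) & (ca2 == ra2)
    cflip = (ca1 == ra2) & (ca2 == ra1)

    action = np.full(len(df), -2, dtype=np.int8)
    action[same | csame] = 0
    action[(flip | cflip) & ~(same | csame)] = 1

    if pal.any():
        if policy == "drop":
            action[pal] = -1
        else:  # freq_resolve
            eaf = df["eaf"].to_numpy()
            reaf = df["reaf"].to_numpy()
            maf = np.minimum(eaf, 1 - eaf)
            hi = pal & (maf > 0.4)
            action[hi] = -1
            lo = pal & ~hi
            # orientation by frequency agreement with the reference
            agree_same = np.abs(eaf - reaf) <= np.abs((1 - eaf) - reaf)
            action[lo & agree_same] = 0
            action[lo & ~agree_same] = 1
    return action


def harmonize(tables: Sequence[SumStatsTable], reference: SumStatsTable,
              ambiguous_policy: str = "freq_resolve",
              ) -> tuple[list[SumStatsTable], HarmonizeReport]:
    """Align every table to the reference allele frame.

    All output tables are restricted to the variants shared (and
    reconcilable) across every input table and the reference, in reference
    order.  Where a table's alleles are swapped relative to the reference,
    ``beta`` and ``z`` are negated and ``eaf`` becomes ``1 − eaf``.
    Complement-strand encodings are folded onto the reference strand.
    Palindromic (A/T, C/G) variants are dropped under ``policy='drop'``;
    under ``'freq_resolve'`` they are dropped only when min(eaf, 1−eaf) >
    0.4 and otherwise oriented by frequency agreement.
    """
    if not tables:
        raise InputError("harmonize requires at least one table")
    if ambiguous_policy not in ("drop", "freq_resolve"):
        raise ConfigurationError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    if reference.df["snp"].duplicated().any():
        raise InputError("reference has duplicate variant ids")

    ref = reference.df[["snp", "a1", "a2", "eaf"]].rename(
        columns={"a1": "ra1", "a2": "ra2", "eaf": "reaf"})
    ref_ids = reference.df["snp"].to_numpy()

    aligned: list[pd.DataFrame] = []
    flips_per_table: list[pd.Series] = []
    strand_dropped: set = set()
    kept_sets: list[set] = []
    for t in tables:
        merged = t.df.merge(ref, on="snp", how="inner")
        action = _orient(merged, ref, ambiguous_policy)
        strand_dropped.update(merged.loc[action == -1, "snp"])
        keep = action >= 0
        out = merged.loc[keep].copy()
        act = action[keep]
        flip = act == 1
        out.loc[flip, "beta"] = -out.loc[flip, "beta"]
        out.loc[flip, "z"] = -out.loc[flip, "z"]
        out.loc[flip, "eaf"] = 1 - out.loc[flip, "eaf"]
        out["a1"] = out["ra1"]
        out["a2"] = out["ra2"]
        out = out.drop(columns=["ra1", "ra2", "reaf"])
        aligned.append(out)
        flips_per_table.append(set(out.loc[flip, "snp"]))
        kept_sets.append(set(out["snp"]))

    shared = set.intersection(*kept_sets) if kept_sets else set()
    order = [s for s in ref_ids if s in shared]
    idx = pd.Index(order, name="snp")

    out_tables = []
    n_flipped = 0
    for t, df, flipped in zip(tables, aligned, flips_per_table):
        df = df.set_index("snp").loc[idx].reset_index()
        out_tables.append(SumStatsTable(t.trait_label, df))
        n_flipped += len(flipped & shared)

    n_kept = len(order)
    n_strand = len(strand_dropped & set(ref_ids))
    n_missing = len(ref_ids) - n_kept - n_strand
    report = HarmonizeReport(n_kept=n_kept, n_flipped=n_flipped,
                             n_strand_dropped=n_strand,
                             n_missing_dropped=n_missing)
    log.info("harmonize: kept %d, flipped %d, strand-dropped %d, missing/irreconcilable %d",
             n_kept, n_flipped, n_strand, n_missing)
    return out_tables, report


def qc_filter(table: SumStatsTable, min_maf: float = 0.01,
              chisq_cap_rule: str = "ldsc_default") -> SumStatsTable:
    """Frequency and extreme-statistic filtering before LD score regression.

    Removes variants with min(eaf, 1−eaf) < ``min_maf``; under the
    ``ldsc_default`` rule additionally removes variants with
    z² > max(80, 0.001·n).  Returns a new table; the input is unmodified.
    """
    if not (0 <= min_maf < 0.5):
        raise ConfigurationError("min_maf must be in [0, 0.5)")
    if chisq_cap_rule not in ("none", "ldsc_default"):
        raise ConfigurationError(f"unknown chisq_cap_rule {chisq_cap_rule!r}")
    df = table.df
    maf = np.minimum(df["eaf"], 1 - df["eaf"])
    keep = maf >= min_maf
    if chisq_cap_rule == "ldsc_default":
        cap = np.maximum(80.0, 0.001 * df["n"])
        keep &= df["z"] ** 2 <= cap
    out = df.loc[keep].reset_index(drop=True)
    if out.empty:
        raise EmptyInputError(f"{table.trait_label}: QC removed all variants")
    n_removed = len(df) - len(out)
    if n_removed:
        log.info("%s: QC removed %d of %d variants",
                 table.trait_label, n_removed, len(df))
    return SumStatsTable(table.trait_label, out)
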