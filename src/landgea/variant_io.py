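"""Genotype matrices: VCF I/O, site/individual/genotype filters, LD pruning, imputation.

The central container is :class:`GenotypeMatrix`, an individuals x loci matrix of
alt-allele dosages (0/1/2, ``NaN`` = missing) together with locus coordinates, a
variant class per locus (SNP or one of the SV classes), and a provenance log that
records every filter applied with its before/after counts.

All filters are pure functions: they return a new matrix and never mutate their
input, and re-applying any filter to its own output is the identity.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    FormatError,
    PreconditionError,
    UnsupportedInputError,
)

SNP_CLASS = "SNP"
SV_CLASSES = ("DEL", "DUP", "INS", "INV", "BND")
VARIANT_CLASSES = (SNP_CLASS, "INDEL") + SV_CLASSES

MISSING = np.nan


def _is_missing(a: np.ndarray) -> np.ndarray:
    return np.isnan(a)


@dataclass
class GenotypeMatrix:
    """Individuals x loci alt-allele dosage matrix with metadata.

    Attributes
    ----------
    dosage : (n, m) float array with values in {0, 1, 2} and NaN for missing.
    individuals : DataFrame indexed by individual id with columns
        ``population`` and ``ecotype`` (ecotype may be NA).
    loci : DataFrame with columns ``locus_id``, ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``, ``variant_class`` and ``multiallelic`` (bool).
    support : optional (n, m) float array of per-genotype support read counts
        (SV panels; NaN where absent).
    filter_log : ordered list of dicts describing applied operations.
    """

    dosage: np.ndarray
    individuals: pd.DataFrame
    loci: pd.DataFrame
    support: np.ndarray | None = None
    filter_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if len(self.individuals) != n or len(self.loci) != m:
            raise FormatError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if (self.loci["pos"] < 1).any():
            raise FormatError("locus positions must be 1-based (>= 1)")
        key = self.loci[["chrom", "pos", "alt"]].astype(str).agg(":".join, axis=1)
        if key.duplicated().any():
            raise FormatError("duplicate (chrom, pos, alt) locus keys")

    # -- basic views -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def locus_ids(self) -> pd.Index:
        return pd.Index(self.loci["locus_id"])

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage, index=self.individuals.index, columns=self.locus_ids
        )

    def site_missingness(self) -> np.ndarray:
        return _is_missing(self.dosage).mean(axis=0)

    def individual_missingness(self) -> np.ndarray:
        return _is_missing(self.dosage).mean(axis=1)

    # -- subsetting helpers (preserve provenance) --------------------------

    def _take(self, ind_mask=None, locus_mask=None) -> "GenotypeMatrix":
        ind_mask = np.ones(self.n_individuals, bool) if ind_mask is None else ind_mask
        locus_mask = np.ones(self.n_loci, bool) if locus_mask is None else locus_mask
        sup = None
        if self.support is not None:
            sup = self.support[np.ix_(ind_mask, locus_mask)]
        return GenotypeMatrix(
            dosage=self.dosage[np.ix_(ind_mask, locus_mask)].copy(),
            individuals=self.individuals.loc[ind_mask].copy(),
            loci=self.loci.loc[locus_mask].reset_index(drop=True),
            support=sup,
            filter_log=copy.deepcopy(self.filter_log),
        )

    def subset_loci(self, locus_ids) -> "GenotypeMatrix":
        mask = self.loci["locus_id"].isin(set(locus_ids)).to_numpy()
        return self._take(locus_mask=mask)

    def _log(self, op: str, n_in: int, n_out: int, **params) -> None:
        self.filter_log.append(
            {"op": op, "n_in": int(n_in), "n_out": int(n_out),
             "n_removed": int(n_in - n_out), **params}
        )


@dataclass
class FreqMatrix:
    """Group (population or population x ecotype) x locus alt-allele frequencies.

    ``freq`` holds frequencies in [0, 1] (NaN where a group has zero genotyped
    alleles at a locus); ``n_alleles`` the matching non-missing allele counts.
    """

    freq: pd.DataFrame
    n_alleles: pd.DataFrame


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

def read_vcf(path, support_field: str | None = None) -> GenotypeMatrix:
    """Read a VCF 4.2 file into a :class:`GenotypeMatrix`.

    Diploid GT is mapped 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing.
    Records with several ALT alleles are kept but flagged ``multiallelic`` so
    that :func:`filter_sites` can drop them. The SV class is taken from
    INFO/SVTYPE when present; otherwise SNP vs INDEL is inferred from REF/ALT
    lengths. ``support_field`` names a per-genotype integer FORMAT field (for
    SV panels, typically ``SR``) to load into ``GenotypeMatrix.support``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns")

    rows, dosage_cols, support_cols = [], [], []
    for v in vcf:
        gts = v.genotypes  # list of [allele0, allele1, ..., phased]
        dos = np.empty(len(samples))
        for i, g in enumerate(gts):
            alleles = g[:-1]
            if len(alleles) != 2:
                raise UnsupportedInputError(
                    f"{path}: non-diploid genotype at {v.CHROM}:{v.POS} "
                    f"(ploidy {len(alleles)})"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                dos[i] = MISSING
            else:
                dos[i] = (alleles[0] > 0) + (alleles[1] > 0)
        alts = v.ALT
        if not alts:
            continue
        svtype = v.INFO.get("SVTYPE")
        if svtype is not None:
            vclass = str(svtype)
        elif len(v.REF) == 1 and len(alts[0]) == 1:
            vclass = SNP_CLASS
        else:
            vclass = "INDEL"
        rows.append(
            {
                "locus_id": v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}",
                "chrom": v.CHROM,
                "pos": int(v.POS),
                "ref": v.REF,
                "alt": ",".join(alts),
                "variant_class": vclass,
                "multiallelic": len(alts) > 1,
            }
        )
        dosage_cols.append(dos)
        if support_field is not None:
            sup = v.format(support_field)
            if sup is None:
                support_cols.append(np.full(len(samples), np.nan))
            else:
                s = sup.astype(float).reshape(len(samples), -1)[:, 0]
                s[s < 0] = np.nan
                support_cols.append(s)

    if not rows:
        raise FormatError(f"{path}: no usable variant records")
    loci = pd.DataFrame(rows)
    dosage = np.column_stack(dosage_cols)
    support = np.column_stack(support_cols) if support_field is not None else None
    individuals = pd.DataFrame(
        {"population": pd.NA, "ecotype": pd.NA}, index=pd.Index(samples, name="individual")
    )
    gm = GenotypeMatrix(dosage=dosage, individuals=individuals, loci=loci, support=support)
    gm._log("read_vcf", gm.n_loci, gm.n_loci, path=Path(path).name)
    return gm


def write_vcf(gm: GenotypeMatrix, path, support_field: str | None = None) -> None:
    """Write the matrix as an uncompressed VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if support_field:
            fh.write(
                f'##FORMAT=<ID={support_field},Number=1,Type=Integer,'
                'Description="Supporting read pairs">\n'
            )
        for chrom in pd.unique(gm.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals.index)
            + "\n"
        )
        fmt = "GT" + (f":{support_field}" if support_field else "")
        for j, locus in gm.loci.iterrows():
            info = (
                f"SVTYPE={locus.variant_class}"
                if locus.variant_class in SV_CLASSES
                else "."
            )
            cells = []
            for i in range(gm.n_individuals):
                d = gm.dosage[i, j]
                gt = "./." if np.isnan(d) else ("0/0", "0/1", "1/1")[int(d)]
                if support_field:
                    s = gm.support[i, j] if gm.support is not None else np.nan
                    cells.append(f"{gt}:{'.' if np.isnan(s) else int(s)}")
                else:
                    cells.append(gt)
            fh.write(
                f"{locus.chrom}\t{locus.pos}\t{locus.locus_id}\t{locus.ref}\t"
                f"{locus.alt}\t.\tPASS\t{info}\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def write_dosage_csv(gm: GenotypeMatrix, path) -> None:
    gm.dosage_frame().to_csv(path, float_format="%.10g")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_sites(
    gm: GenotypeMatrix, biallelic_only: bool = True, max_site_missing: float = 0.30
) -> GenotypeMatrix:
    """Drop non-biallelic/indel records (when requested) and high-missingness loci.

    A locus survives the missingness rule only if its missing fraction is
    strictly below ``max_site_missing`` (a site with exactly the threshold is
    removed).
    """
    if not 0 <= max_site_missing <= 1:
        raise ConfigurationError(f"max_site_missing {max_site_missing} not in [0, 1]")
    keep = np.ones(gm.n_loci, bool)
    n_biallelic_removed = 0
    if biallelic_only:
        bad = (
            gm.loci["multiallelic"].to_numpy()
            | (gm.loci["variant_class"] == "INDEL").to_numpy()
        )
        n_biallelic_removed = int(bad.sum())
        keep &= ~bad
    miss = gm.site_missingness()
    keep_miss = miss < max_site_missing
    n_missing_removed = int((keep & ~keep_miss).sum())
    keep &= keep_miss
    out = gm._take(locus_mask=keep)
    out._log(
        "filter_sites", gm.n_loci, out.n_loci,
        biallelic_only=biallelic_only, max_site_missing=max_site_missing,
        removed_non_biallelic=n_biallelic_removed, removed_missing=n_missing_removed,
    )
    return out


def filter_individuals(gm: GenotypeMatrix, max_ind_missing: float = 0.30) -> GenotypeMatrix:
    """Remove individuals whose missing fraction exceeds the threshold (strict >)."""
    if not 0 <= max_ind_missing <= 1:
        raise ConfigurationError(f"max_ind_missing {max_ind_missing} not in [0, 1]")
    keep = gm.individual_missingness() <= max_ind_missing
    out = gm._take(ind_mask=keep)
    out._log(
        "filter_individuals", gm.n_individuals, out.n_individuals,
        max_ind_missing=max_ind_missing,
    )
    return out


def recode_low_support(
    gm: GenotypeMatrix, min_support: int = 3, support_field: str = "SR"
) -> GenotypeMatrix:
    """Set genotypes with fewer than ``min_support`` supporting reads to missing.

    The boundary is inclusive: support == min_support is kept. Callers
    typically follow with ``filter_sites(max_site_missing=0.20)`` for SV
    panels.
    """
    if gm.support is None:
        raise ConfigurationError(
            f"support field {support_field!r} not loaded; pass support_field to read_vcf"
        )
    out = gm._take()
    low = (out.support < min_support) & ~np.isnan(out.support)
    out.dosage[low] = MISSING
    out._log(
        "recode_low_support", gm.n_loci, out.n_loci,
        min_support=min_support, n_genotypes_recoded=int(low.sum()),
    )
    return out


def _window_starts(pos_min: int, pos_max: int, window_bp: int) -> range:
    step = max(window_bp // 2, 1)
    return range(int(pos_min), int(pos_max) + 1, step)


def ld_prune(
    gm: GenotypeMatrix, r2_threshold: float = 0.5, window_bp: int = 200_000
) -> GenotypeMatrix:
    """Greedy LD pruning within sliding windows.

    Loci must be sorted by (chrom, pos). Windows of ``window_bp`` slide by half
    the window size; inside each window a left-to-right scan removes the later
    locus of any surviving pair whose squared Pearson correlation of dosages
    (pairwise-complete over non-missing individuals) exceeds the threshold.
    Idempotent: pruned output survives a second pass unchanged.
    """
    loci = gm.loci
    sorted_ok = all(
        (g["pos"].is_monotonic_increasing) for _, g in loci.groupby("chrom", sort=False)
    )
    if not sorted_ok:
        raise PreconditionError("loci must be sorted by (chrom, pos) before ld_prune")

    removed = np.zeros(gm.n_loci, bool)
    for chrom, grp in loci.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        for start in _window_starts(pos.min(), pos.max(), window_bp):
            in_win = (pos >= start) & (pos < start + window_bp)
            widx = idx[in_win]
            if len(widx) < 2:
                continue
            sub = pd.DataFrame(gm.dosage[:, widx])
            r = sub.corr(min_periods=2).to_numpy()
            r2 = r * r
            for a in range(len(widx)):
                if removed[widx[a]]:
                    continue
                for b in range(a + 1, len(widx)):
                    if removed[widx[b]]:
                        continue
                    if np.isfinite(r2[a, b]) and r2[a, b] > r2_threshold:
                        removed[widx[b]] = True
    out = gm._take(locus_mask=~removed)
    out._log(
        "ld_prune", gm.n_loci, out.n_loci,
        r2_threshold=r2_threshold, window_bp=window_bp,
    )
    return out


def exclude_regions(gm: GenotypeMatrix, bed_path) -> GenotypeMatrix:
    """Remove loci whose 1-based position falls inside any BED interval.

    BED intervals are 0-based half-open, so interval (start, end] in 1-based
    coordinates: a locus at pos is removed iff start < pos <= end.
    """
    from intervaltree import IntervalTree

    bed = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
    )
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in bed.groupby("chrom"):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"]) if e > s
        )
    keep = np.ones(gm.n_loci, bool)
    for j, (chrom, pos) in enumerate(zip(gm.loci["chrom"], gm.loci["pos"])):
        tree = trees.get(str(chrom))
        if tree is not None and tree.overlaps_point(int(pos) - 1):
            keep[j] = False
    out = gm._take(locus_mask=keep)
    out._log("exclude_regions", gm.n_loci, out.n_loci, bed=Path(bed_path).name)
    return out


def impute_mode(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing entries with the locus's modal dosage (ties -> smallest).

    Raises :class:`DegenerateDataError` for an all-missing locus.
    """
    out = gm._take()
    d = out.dosage
    miss = _is_missing(d)
    if miss.any():
        counts = np.stack([(d == v).sum(axis=0) for v in (0.0, 1.0, 2.0)])
        all_missing = counts.sum(axis=0) == 0
        if (all_missing & miss.any(axis=0)).any():
            bad = out.loci.loc[all_missing, "locus_id"].tolist()
            raise DegenerateDataError(f"cannot impute all-missing loci: {bad[:5]}")
        mode = np.argmax(counts, axis=0).astype(float)  # argmax -> smallest on ties
        jj = np.where(miss)[1]
        d[miss] = mode[jj]
    out._log("impute_mode", gm.n_loci, out.n_loci,
             n_imputed=int(miss.sum()))
    return out


def allele_frequencies(gm: GenotypeMatrix, grouping) -> FreqMatrix:
    """Per-group alt-allele frequencies: sum(dosage) / (2 x non-missing count).

    ``grouping`` maps individual id -> group label (dict or Series). Cells
    where a group has no genotyped individuals at a locus are NaN.
    """
    groups = pd.Series(grouping).reindex(gm.individuals.index)
    if groups.isna().any():
        missing = gm.individuals.index[groups.isna()].tolist()
        raise ConfigurationError(f"individuals without group label: {missing[:5]}")
    d = gm.dosage
    obs = ~_is_missing(d)
    labels = pd.unique(groups)
    freq_rows, count_rows = [], []
    for g in labels:
        sel = (groups == g).to_numpy()
        n_alleles = 2.0 * obs[sel].sum(axis=0)
        alt = np.nansum(d[sel], axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        freq_rows.append(f)
        count_rows.append(n_alleles)
    idx = pd.Index(labels, name="group")
    return FreqMatrix(
        freq=pd.DataFrame(freq_rows, index=idx, columns=gm.locus_ids),
        n_alleles=pd.DataFrame(count_rows, index=idx, columns=gm.locus_ids),
    )
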