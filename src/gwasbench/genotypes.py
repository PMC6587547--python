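"""Genotype matrices: loading, filtering, encoding, and per-marker summaries.

The central container is :class:`GenotypeMatrix`, a markers x individuals
dosage matrix (0/1/2 copies of the counted allele, ``NaN`` for missing calls)
with a marker map (id, chromosome, position in bp, counted/other allele) and
sample ids.  Three on-disk dialects are supported: VCF (GT field only, via
cyvcf2), HapMap-style tab-delimited text, and a plain dosage-matrix text
format documented in :func:`write_dosage_matrix`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "load_genotypes",
    "write_dosage_matrix",
    "summarize_markers",
    "filter_markers",
    "impute_missing",
    "recode_to_minor",
]

MARKER_COLUMNS = ["id", "chrom", "pos", "counted", "other"]

# IUPAC ambiguity codes for heterozygous diploid calls (HapMap GBS convention)
_IUPAC_HET = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}


@dataclass
class GenotypeMatrix:
    """Markers x individuals dosage matrix with marker map and sample ids.

    ``dosages[i, j]`` counts copies of marker *i*'s counted allele carried by
    individual *j*; missing calls are ``NaN``.  Markers are sorted by
    (chromosome, position) at construction and positions must be
    non-decreasing within a chromosome (ties arise from split
    multi-allelic sites).
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (markers x individuals) array")
        if len(self.markers) != self.dosages.shape[0]:
            raise ValueError(
                f"marker table has {len(self.markers)} rows but dosage matrix "
                f"has {self.dosages.shape[0]}"
            )
        if len(self.samples) != self.dosages.shape[1]:
            raise ValueError(
                f"{len(self.samples)} sample ids for {self.dosages.shape[1]} columns"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("non-missing dosages must lie in [0, 2]")
        self.markers = self.markers.reset_index(drop=True)
        order = np.lexsort((self.markers["pos"].to_numpy(),
                            self.markers["chrom"].astype(str).to_numpy()))
        if not np.array_equal(order, np.arange(len(order))):
            self.markers = self.markers.iloc[order].reset_index(drop=True)
            self.dosages = self.dosages[order]
        # ties are tolerated (split multi-allelic sites share a position)
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"non-increasing positions on {chrom}")

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[1]

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.dosages).any()

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[index],
                              self.markers.iloc[index].reset_index(drop=True),
                              list(self.samples))

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[:, index], self.markers.copy(),
                              [self.samples[i] for i in np.asarray(index)])


def load_genotypes(path: str | os.PathLike, format: str = "dosage-matrix",
                   multiallelic: str = "reject") -> GenotypeMatrix:
    """Read a genotype file into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    format
        One of ``vcf``, ``hapmap``, ``dosage-matrix``.
    multiallelic
        Policy for sites with more than one ALT allele: ``reject`` raises,
        ``split`` emits one biallelic marker per ALT allele.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "vcf":
        return _load_vcf(path, multiallelic)
    if format == "hapmap":
        return _load_hapmap(path)
    if format == "dosage-matrix":
        return _load_dosage_matrix(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _load_vcf(path: str, multiallelic: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        alts = var.ALT
        if len(alts) > 1 and multiallelic == "reject":
            raise ValueError(
                f"multi-allelic site {var.ID or var.CHROM + ':' + str(var.POS)} "
                "(pass multiallelic='split' to expand)")
        # gt_types with gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        if len(alts) <= 1:
            d = var.gt_types.astype(float)
            d[d == 3] = np.nan
            rows.append(d)
            meta.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS,
                         alts[0] if alts else var.REF, var.REF))
        else:  # split: count each alt allele separately from raw genotypes
            gts = np.array(var.genotypes, dtype=object)
            for k, alt in enumerate(alts, start=1):
                d = np.full(len(samples), np.nan)
                for j, g in enumerate(gts):
                    a = [x for x in g[:-1]]
                    if any(x < 0 for x in a):
                        continue
                    d[j] = sum(1 for x in a if x == k)
                rows.append(d)
                meta.append((f"{var.ID or var.CHROM}_{var.POS}_{alt}", var.CHROM,
                             var.POS, alt, var.REF))
    if not rows:
        raise ValueError(f"no variant records in {path}")
    markers = pd.DataFrame(meta, columns=MARKER_COLUMNS)
    return GenotypeMatrix(np.vstack(rows), markers, samples)


def _load_hapmap(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 12:
            raise ValueError(f"{path}:1: HapMap header needs 11 metadata columns "
                             "plus at least one sample")
        samples = header[11:]
        rows, meta = [], []
        for ln, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != 11 + len(samples):
                raise ValueError(f"{path}:{ln}: expected {11 + len(samples)} "
                                 f"fields, found {len(f)}")
            alleles = f[1].split("/")
            if len(alleles) != 2:
                raise ValueError(f"{path}:{ln}: marker {f[0]} is not biallelic "
                                 f"({f[1]})")
            ref, alt = alleles
            d = np.full(len(samples), np.nan)
            for j, call in enumerate(f[11:]):
                d[j] = _hapmap_dosage(call, ref, alt, f"{path}:{ln}")
            rows.append(d)
            meta.append((f[0], f[2], int(f[3]), alt, ref))
    if not rows:
        raise ValueError(f"no marker records in {path}")
    return GenotypeMatrix(np.vstack(rows),
                          pd.DataFrame(meta, columns=MARKER_COLUMNS), samples)


def _hapmap_dosage(call: str, ref: str, alt: str, where: str) -> float:
    call = call.upper()
    if call in ("N", "NN", "--", "./.", "NA"):
        return np.nan
    if len(call) == 1:
        call = _IUPAC_HET.get(call, call * 2)
    if len(call) != 2:
        raise ValueError(f"{where}: unparseable genotype call {call!r}")
    d = 0.0
    for a in call:
        if a == alt:
            d += 1
        elif a != ref:
            raise ValueError(f"{where}: allele {a!r} not in {ref}/{alt}")
    return d


def _load_dosage_matrix(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
        if header[:5] != MARKER_COLUMNS:
            raise ValueError(f"{path}:1: header must start with "
                             f"{MARKER_COLUMNS}, found {header[:5]}")
        samples = header[5:]
        rows, meta = [], []
        for ln, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != 5 + len(samples):
                raise ValueError(f"{path}:{ln}: expected {5 + len(samples)} "
                                 f"fields, found {len(f)}")
            try:
                d = np.array([np.nan if x == "NA" else float(x) for x in f[5:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: bad dosage value ({exc})") from None
            rows.append(d)
            meta.append((f[0], f[1], int(f[2]), f[3], f[4]))
    if not rows:
        raise ValueError(f"no marker rows in {path}")
    return GenotypeMatrix(np.vstack(rows),
                          pd.DataFrame(meta, columns=MARKER_COLUMNS), samples)


def write_dosage_matrix(G: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write the dosage-matrix text dialect.

    Tab-delimited; header row ``id chrom pos counted other <sample ids...>``,
    then one row per marker.  Missing calls are written as ``NA``; integer
    dosages are written without a decimal point so the format round-trips
    bit-identically.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(MARKER_COLUMNS + list(G.samples)) + "\n")
        for i in range(G.n_markers):
            m = G.markers.iloc[i]
            vals = []
            for x in G.dosages[i]:
                if np.isnan(x):
                    vals.append("NA")
                elif float(x).is_integer():
                    vals.append(str(int(x)))
                else:
                    vals.append(repr(float(x)))
            fh.write("\t".join([str(m["id"]), str(m["chrom"]), str(int(m["pos"])),
                                str(m["counted"]), str(m["other"])] + vals) + "\n")


def summarize_markers(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker MAF, missing rate, and heterozygosity rate.

    MAF is ``min(f, 1-f)`` with *f* the counted-allele frequency over
    non-missing calls only; het rate counts dosage-1 calls among non-missing.
    """
    D = G.dosages
    miss = np.isnan(D)
    n_called = (~miss).sum(axis=1)
    if np.any(n_called == 0):
        bad = G.markers["id"].iloc[int(np.argmax(n_called == 0))]
        raise ValueError(f"marker {bad} has no non-missing calls")
    f = np.nansum(D, axis=1) / (2.0 * n_called)
    maf = np.minimum(f, 1.0 - f)
    het = (D == 1).sum(axis=1) / n_called
    out = pd.DataFrame({
        "id": G.markers["id"].to_numpy(),
        "maf": maf,
        "missing_rate": miss.mean(axis=1),
        "het_rate": het,
    })
    return out


def filter_markers(G: GenotypeMatrix, max_missing: float = 1.0,
                   max_het: float = 1.0, min_maf: float = 0.0) -> GenotypeMatrix:
    """Retain markers with missing_rate <= max_missing, het_rate <= max_het
    and MAF >= min_maf (boundary values kept; removal is strict), preserving
    marker order."""
    for name, v in (("max_missing", max_missing), ("max_het", max_het),
                    ("min_maf", min_maf)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    s = summarize_markers(G)
    keep = ((s["missing_rate"] <= max_missing) & (s["het_rate"] <= max_het)
            & (s["maf"] >= min_maf)).to_numpy()
    if not keep.any():
        raise ValueError("all markers removed by filtering thresholds")
    return G.take_markers(np.flatnonzero(keep))


def impute_missing(G: GenotypeMatrix, method: str = "marker-mean") -> GenotypeMatrix:
    """Fill missing calls per marker.

    ``marker-mean`` substitutes the marker's mean dosage (fractional values in
    [0, 2]); ``marker-mode`` substitutes the most frequent integer dosage
    (ties broken toward the smaller dosage).
    """
    D = G.dosages.copy()
    miss = np.isnan(D)
    if not miss.any():
        return G
    if np.any(miss.all(axis=1)):
        bad = G.markers["id"].iloc[int(np.argmax(miss.all(axis=1)))]
        raise ValueError(f"marker {bad} has no non-missing calls to impute from")
    if method == "marker-mean":
        fill = np.nanmean(D, axis=1)
    elif method == "marker-mode":
        fill = np.empty(G.n_markers)
        for i in np.flatnonzero(miss.any(axis=1)):
            vals, counts = np.unique(D[i][~miss[i]], return_counts=True)
            fill[i] = vals[np.argmax(counts)]
    else:
        raise ValueError(f"unknown imputation method: {method!r}")
    rows = np.nonzero(miss)[0]
    D[miss] = fill[rows]
    return GenotypeMatrix(D, G.markers.copy(), list(G.samples))


def recode_to_minor(G: GenotypeMatrix) -> GenotypeMatrix:
    """Recode so the counted allele is the minor allele at every marker
    (dosage x -> 2-x where the counted-allele frequency exceeds 0.5)."""
    s = summarize_markers(G)
    D = G.dosages.copy()
    markers = G.markers.copy()
    f = np.nansum(D, axis=1) / (2.0 * (~np.isnan(D)).sum(axis=1))
    flip = f > 0.5
    D[flip] = 2.0 - D[flip]
    sw = markers.loc[flip, "counted"].copy()
    markers.loc[flip, "counted"] = markers.loc[flip, "other"]
    markers.loc[flip, "other"] = sw
    return GenotypeMatrix(D, markers, list(G.samples))
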