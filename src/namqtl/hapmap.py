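"""HapMap genotype I/O, numeric 0/1/2 encoding, MAF filtering, imputation.

The HapMap text format is tab-delimited with 11 marker-metadata columns
(rs#, alleles, chrom, pos, strand, assembly#, center, protLSID, assayLSID,
panelLSID, QCcode) followed by one column per sample. Two call dialects
are accepted: two-letter diploid calls ("AA", "AT", "NN") and
single-letter IUPAC codes where a heterozygote is the ambiguity code
("A", "W", "N"). Strand is ignored; alleles are taken as printed.

Numeric coding is relative to the biparental parents: 0 = homozygous for
the common reference parent's allele, 1 = heterozygous, 2 = homozygous
for the alternative parent's allele; anything matching neither parent is
set missing (counted and reported via a warning).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import GeneticMap, GenotypeMatrix
from .simulate import PHYSICAL_BP_PER_CM, ril_recombination_fraction

__all__ = [
    "HapMapParseError",
    "read_hapmap",
    "write_hapmap",
    "encode_numeric",
    "filter_maf",
    "impute_missing",
]

HAPMAP_COLUMNS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]

_IUPAC = {
    "A": "AA", "C": "CC", "G": "GG", "T": "TT",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "N": "NN", "-": "NN",
}


class HapMapParseError(ValueError):
    """Malformed HapMap input; the message names the offending line."""


def read_hapmap(path, cm_per_mb: float = 1.0):
    """Read a HapMap genotype file.

    Returns ``(gmap, calls)`` where ``calls`` is a DataFrame of verbatim
    call strings (markers x samples, indexed by marker id) carrying the
    printed ``alleles`` column as ``calls.attrs["alleles"]``. Genetic
    positions are derived from physical positions at ``cm_per_mb``
    (HapMap files carry no genetic coordinate). Markers are sorted by
    (chromosome, position); unsorted input sorts with a warning.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise HapMapParseError("line 1: empty header")
        cols = header.split("\t")
        if [c.lower() for c in cols[:11]] != [c.lower() for c in HAPMAP_COLUMNS]:
            raise HapMapParseError(
                "line 1: expected the 11 standard HapMap metadata columns, got "
                + ", ".join(cols[:11])
            )
        samples = cols[11:]
        if not samples:
            raise HapMapParseError("line 1: no sample columns")
        ncol = len(cols)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != ncol:
                raise HapMapParseError(
                    f"line {lineno}: expected {ncol} fields, found {len(parts)}"
                )
            rows.append(parts)
    if not rows:
        raise HapMapParseError("no marker rows")
    marker = np.array([r[0] for r in rows], dtype=object)
    alleles = np.array([r[1] for r in rows], dtype=object)
    try:
        chrom = np.array([int(r[2]) for r in rows])
        pos = np.array([int(r[3]) for r in rows], dtype=np.int64)
    except ValueError as exc:
        raise HapMapParseError(f"non-numeric chrom/pos field: {exc}") from exc
    calls = np.array([r[11:] for r in rows], dtype=object)
    order = np.lexsort((pos, chrom))
    if not np.array_equal(order, np.arange(len(rows))):
        warnings.warn("HapMap input was not sorted by (chrom, pos); sorting", UserWarning)
        marker, alleles, chrom, pos, calls = (
            marker[order], alleles[order], chrom[order], pos[order], calls[order],
        )
    gmap = GeneticMap(marker, chrom, _genetic_from_physical(chrom, pos, cm_per_mb), pos)
    df = pd.DataFrame(calls, index=marker, columns=samples)
    df.attrs["alleles"] = alleles
    return gmap, df


def _genetic_from_physical(chrom, pos, cm_per_mb):
    g = np.empty(len(pos), dtype=float)
    for c in np.unique(chrom):
        sel = chrom == c
        p = pos[sel]
        g[sel] = (p - p.min()) / 1e6 * cm_per_mb
    return g


def write_hapmap(geno: GenotypeMatrix, path) -> None:
    """Write numeric codes as two-letter diploid HapMap calls.

    Uses the matrix's per-marker ref/alt alleles (defaults A/C when
    absent); missing codes become "NN".
    """
    ref = geno.ref_alleles if geno.ref_alleles is not None else np.full(geno.n_markers, "A", dtype=object)
    alt = geno.alt_alleles if geno.alt_alleles is not None else np.full(geno.n_markers, "C", dtype=object)
    gmap = geno.gmap
    with open(path, "w") as fh:
        fh.write("\t".join(HAPMAP_COLUMNS + list(geno.ril_ids)) + "\n")
        for j in range(geno.n_markers):
            calls = []
            for x in geno.codes[:, j]:
                if np.isnan(x):
                    calls.append("NN")
                elif x == 0:
                    calls.append(ref[j] + ref[j])
                elif x == 2:
                    calls.append(alt[j] + alt[j])
                else:
                    calls.append(ref[j] + alt[j])
            meta = [
                str(gmap.marker_id[j]),
                f"{ref[j]}/{alt[j]}",
                str(gmap.chromosome[j]),
                str(gmap.physical_pos[j]),
                "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ]
            fh.write("\t".join(meta + calls) + "\n")


def _normalize_call(call: str) -> str:
    call = call.strip().upper()
    if len(call) == 1:
        return _IUPAC.get(call, "NN")
    if len(call) == 2:
        return call
    return "NN"


def encode_numeric(
    calls: pd.DataFrame,
    gmap: GeneticMap,
    reference_parent_alleles: Sequence,
    alternative_parent_alleles,
    families: Mapping | None = None,
    family: str = "fam1",
    ref_parent: str = "B73",
) -> GenotypeMatrix:
    """Convert diploid calls to the 0/1/2 numeric coding.

    ``reference_parent_alleles`` is one nucleotide per marker (the common
    parent's homozygous allele). ``alternative_parent_alleles`` is either
    one nucleotide per marker (shared across families) or a mapping
    ``family -> per-marker alleles``; in the latter case ``families`` must
    map each sample to its family. Calls matching neither parent become
    missing (counted in a warning); markers monomorphic between the
    parents are dropped with a warning.
    """
    samples = list(calls.columns)
    fam_of = {s: family for s in samples} if families is None else dict(families)
    for s in samples:
        if s not in fam_of:
            raise ValueError(f"sample {s!r} has no family label")
    ref = np.asarray(reference_parent_alleles, dtype=object)
    if isinstance(alternative_parent_alleles, Mapping):
        alt_by_fam = {f: np.asarray(a, dtype=object) for f, a in alternative_parent_alleles.items()}
    else:
        shared = np.asarray(alternative_parent_alleles, dtype=object)
        alt_by_fam = {f: shared for f in set(fam_of.values())}
    m = len(calls)
    if len(ref) != m or any(len(a) != m for a in alt_by_fam.values()):
        raise ValueError("parent allele vectors must have one entry per marker")

    raw = calls.to_numpy(dtype=object)
    norm = np.empty_like(raw)
    for i in range(m):
        for k in range(raw.shape[1]):
            norm[i, k] = _normalize_call(str(raw[i, k]))

    codes = np.full((len(samples), m), np.nan)
    nonparental = 0
    for k, s in enumerate(samples):
        alt = alt_by_fam[fam_of[s]]
        for i in range(m):
            a, b = norm[i, k][0], norm[i, k][1]
            if "N" in (a, b):
                continue
            pair = {a, b}
            if pair == {ref[i]}:
                codes[k, i] = 0.0
            elif pair == {alt[i]}:
                codes[k, i] = 2.0
            elif pair == {ref[i], alt[i]}:
                codes[k, i] = 1.0
            else:
                nonparental += 1
    if nonparental:
        warnings.warn(
            f"{nonparental} calls matched neither parent and were set missing",
            UserWarning,
        )
    # markers monomorphic between parents (in any family) are uninformative
    mono = np.zeros(m, dtype=bool)
    for alt in alt_by_fam.values():
        mono |= ref == alt
    if mono.any():
        warnings.warn(
            f"dropped {int(mono.sum())} markers monomorphic between the parents",
            UserWarning,
        )
    keep = np.flatnonzero(~mono)
    gm = GenotypeMatrix(
        codes[:, keep],
        np.array(samples, dtype=object),
        np.array([fam_of[s] for s in samples], dtype=object),
        gmap.subset(keep),
        ref_parent=ref_parent,
        ref_alleles=ref[keep],
        alt_alleles=None,
    )
    return gm


def filter_maf(geno: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Remove markers whose minor allele frequency is below ``threshold``.

    Allele frequencies are computed on non-missing calls; a heterozygote
    (code 1) contributes one copy of each allele. A MAF exactly equal to
    the threshold is retained.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    codes = geno.codes
    nonmiss = ~np.isnan(codes)
    n_alleles = 2.0 * nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.nansum(codes, axis=0) / n_alleles
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    maf = np.where(n_alleles > 0, maf, 0.0)
    keep = np.flatnonzero(maf >= threshold)
    return geno.subset_markers(keep)


def impute_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Impute missing codes from each RIL's flanking informative markers.

    For a missing call, the nearest non-missing homozygous (0/2) flanking
    markers on the same chromosome of the same RIL determine the
    conditional state distribution under the two-state RIL transmission
    chain (switch probability R = 2r/(1+2r) over the cM distance); the
    expected code 2*P(alt) is rounded to the nearest code in {0, 1, 2}.
    With a single informative flank the expectation degenerates to that
    neighbour's code (for nearby markers). Heterozygous neighbours are
    uninformative about the chain state and are skipped. A RIL with no
    informative marker on a chromosome gets code 1 (prior expectation)
    with a warning. Observed codes are never altered; the returned matrix
    carries an ``imputed`` mask.
    """
    codes = geno.codes.copy()
    miss = np.isnan(codes)
    if not miss.any():
        out = geno.subset_rils(np.arange(geno.n_rils))
        out.imputed = np.zeros_like(miss)
        return out

    # warn (per spec contract) about markers fully missing within a family
    for fam in geno.families():
        rows = geno.rows_of(fam)
        fully = np.flatnonzero(miss[rows].all(axis=0))
        if fully.size:
            warnings.warn(
                f"family {fam}: {fully.size} markers fully missing; imputed "
                "from flanking markers per RIL",
                UserWarning,
            )

    gmap = geno.gmap
    uninformative_rows = 0
    for c in np.unique(gmap.chromosome):
        cols = np.flatnonzero(gmap.chromosome == c)
        cm = gmap.genetic_pos[cols]
        sub = codes[:, cols]
        for irow in range(sub.shape[0]):
            row = sub[irow]
            missing_idx = np.flatnonzero(np.isnan(row))
            if missing_idx.size == 0:
                continue
            info = np.flatnonzero((row == 0.0) | (row == 2.0))
            if info.size == 0:
                row[missing_idx] = 1.0
                uninformative_rows += 1
                continue
            for j in missing_idx:
                left = info[info < j]
                right = info[info > j]
                w = np.ones(2)  # [P(state 0), P(state 2)] up to normalization
                if left.size:
                    l = left[-1]
                    R = ril_recombination_fraction(cm[j] - cm[l])
                    same = 0 if row[l] == 0.0 else 1
                    w[same] *= 1.0 - R
                    w[1 - same] *= R
                if right.size:
                    r_ = right[0]
                    R = ril_recombination_fraction(cm[r_] - cm[j])
                    same = 0 if row[r_] == 0.0 else 1
                    w[same] *= 1.0 - R
                    w[1 - same] *= R
                p_alt = w[1] / (w[0] + w[1])
                row[j] = float(np.rint(2.0 * p_alt))
        codes[:, cols] = sub
    if uninformative_rows:
        warnings.warn(
            f"{uninformative_rows} RIL-chromosomes had no informative marker; "
            "filled with the prior expectation (code 1)",
            UserWarning,
        )
    out = GenotypeMatrix(
        codes, geno.ril_ids, geno.family, gmap,
        ref_parent=geno.ref_parent, alt_parents=dict(geno.alt_parents),
        ref_alleles=geno.ref_alleles, alt_alleles=geno.alt_alleles,
        imputed=miss,
    )
    return out
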