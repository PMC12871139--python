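"""Shared data model and readers/writers for the standard formats the pipeline touches.

The in-memory genotype container is :class:`GenotypeMatrix`: a samples × variants
matrix of ALT-allele dosages (0/1/2, ``-1`` for missing) plus a variant table.
Coordinates are 1-based inclusive throughout, matching VCF.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1  # dosage sentinel

GROUP_LABELS = ("parent1", "parent2", "hybrid", "unknown")


class FormatError(ValueError):
    """A file does not conform to its accepted dialect."""


class EmptyInputError(ValueError):
    """A reader retained zero usable records."""


class ConsistencyError(ValueError):
    """Sample identifiers disagree across input tables."""


@dataclass
class GenotypeMatrix:
    """ALT-allele dosage matrix with its variant table.

    Parameters
    ----------
    samples : list of str
        Sample identifiers (columns of the VCF).
    variants : pandas.DataFrame
        One row per retained site with columns ``chrom, pos, ref, alt`` and,
        when invariant sites are kept, boolean ``is_variant``.
    dosage : ndarray of int8, shape (n_samples, n_variants)
        ALT-allele counts; ``-1`` marks a missing genotype.  Any GT containing
        ``.`` (including half-calls) is missing.
    all_sites : bool
        True when invariant sites were retained (pixy-style denominator input).
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    all_sites: bool = False
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage codes restricted to {0,1,2,-1}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def sample_indices(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"sample {e} not in genotype matrix") from e

    def subset_samples(self, ids) -> "GenotypeMatrix":
        idx = self.sample_indices(ids)
        return GenotypeMatrix(
            [self.samples[i] for i in idx],
            self.variants.reset_index(drop=True),
            self.dosage[idx],
            all_sites=self.all_sites,
        )

    def subset_variants(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            list(self.samples),
            self.variants.loc[mask].reset_index(drop=True),
            self.dosage[:, mask],
            all_sites=self.all_sites,
        )


_NUCS = frozenset("ACGT")


def read_vcf(path, keep_invariant: bool = False) -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are retained; multi-allelic and indel records
    are skipped with a logged count.  GT is parsed regardless of phasing
    separator; half-calls are treated as missing.  With ``keep_invariant``,
    records with a missing/absent ALT ("all-sites" dialect) are kept and
    flagged ``is_variant=False``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(os.fspath(path), gts012=False)
    except Exception as e:
        raise FormatError(f"cannot parse VCF {path}: {e}") from e
    samples = list(vcf.samples)
    chroms, poss, refs, alts, isvar = [], [], [], [], []
    rows = []
    n_skipped = 0
    for rec in vcf:
        alt = rec.ALT
        if len(alt) == 0 or (len(alt) == 1 and alt[0] in (".", "<NON_REF>", "*")):
            if not keep_invariant or len(rec.REF) != 1:
                n_skipped += 1
                continue
            a = "."
            variant = False
        elif len(alt) != 1 or len(rec.REF) != 1 or len(alt[0]) != 1 \
                or alt[0] not in _NUCS or rec.REF not in _NUCS:
            n_skipped += 1
            continue
        else:
            a = alt[0]
            variant = True
        g = np.array(rec.genotypes, dtype=int)  # (n, 3): a1, a2, phased
        allele = g[:, :2]
        miss = (allele < 0).any(axis=1)
        dose = allele.clip(min=0).sum(axis=1).astype(np.int8)
        dose[miss] = MISSING
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(a)
        isvar.append(variant)
        rows.append(dose)
    if not rows:
        raise EmptyInputError(f"no biallelic SNP records retained from {path}")
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": np.array(poss, dtype=np.int64),
         "ref": refs, "alt": alts}
    )
    if keep_invariant:
        variants["is_variant"] = isvar
    order = np.lexsort((variants["pos"].to_numpy(),
                        variants["chrom"].to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    dosage = np.column_stack(rows)[:, order] if rows else np.zeros((len(samples), 0), np.int8)
    return GenotypeMatrix(samples, variants, dosage,
                          all_sites=keep_invariant, n_skipped=n_skipped)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GT-only VCF 4.2."""
    var = gm.variants
    contigs = list(dict.fromkeys(var["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hybridzone\n")
        for c in contigs:
            end = int(var.loc[var["chrom"] == c, "pos"].max()) if len(var) else 1
            fh.write(f"##contig=<ID={c},length={end + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                "FORMAT"] + list(gm.samples)
        fh.write("\t".join(cols) + "\n")
        for j in range(gm.n_variants):
            row = var.iloc[j]
            gts = "\t".join(_GT_STR[int(d)] for d in gm.dosage[:, j])
            line = f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT"
            fh.write(line + ("\t" + gts if gm.n_samples else "") + "\n")


def read_sample_table(path) -> pd.DataFrame:
    """Read the sample metadata TSV: sample, group, elevation_m [, admixture]."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns or "group" not in df.columns:
        raise FormatError("sample table requires 'sample' and 'group' columns")
    bad = set(df["group"]) - set(GROUP_LABELS)
    if bad:
        raise FormatError(f"unknown group labels {sorted(bad)}")
    if df["sample"].duplicated().any():
        raise FormatError("duplicate sample ids in sample table")
    return df


def read_trait_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample" not in df.columns:
        raise FormatError("trait table requires a 'sample' column")
    return df


def read_spectra(path) -> pd.DataFrame:
    """Read a spectra CSV (first column wavelength in nm, one column per sample).

    The wavelength grid must be strictly ascending; negative reflectance is
    clipped to 0.
    """
    df = pd.read_csv(path)
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise FormatError("wavelength grid must be strictly ascending")
    out = df.copy()
    out.iloc[:, 1:] = df.iloc[:, 1:].clip(lower=0.0)
    out = out.rename(columns={df.columns[0]: "wavelength"})
    return out


def read_gff3_genes(path) -> pd.DataFrame:
    """Reduce a GFF3 to one interval per gene: the longest isoform (mRNA).

    Genes without mRNA children keep their own interval.  Returns a DataFrame
    with columns ``gene, chrom, start, end`` sorted by (chrom, start).
    """
    import gffutils

    db = gffutils.create_db(os.fspath(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    recs = []
    for gene in db.features_of_type("gene"):
        best = None
        for mrna in db.children(gene, featuretype="mRNA"):
            length = mrna.end - mrna.start + 1
            if best is None or length > best[0]:
                best = (length, mrna.start, mrna.end)
        start, end = (best[1], best[2]) if best else (gene.start, gene.end)
        recs.append((gene.id, gene.seqid, start, end))
    df = pd.DataFrame(recs, columns=["gene", "chrom", "start", "end"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def read_tables(meta_path=None, traits_path=None, spectra_path=None,
                gff_path=None, check_consistency: bool = True):
    """Load the side tables, cross-checking sample ids where applicable."""
    meta = read_sample_table(meta_path) if meta_path else None
    traits = read_trait_table(traits_path) if traits_path else None
    spectra = read_spectra(spectra_path) if spectra_path else None
    genes = read_gff3_genes(gff_path) if gff_path else None
    if check_consistency and meta is not None:
        known = set(meta["sample"])
        if traits is not None:
            extra = set(traits["sample"]) - known
            if extra:
                raise ConsistencyError(
                    f"trait table samples absent from metadata: {sorted(extra)[:5]}")
        if spectra is not None:
            extra = set(spectra.columns[1:]) - known
            if extra:
                raise ConsistencyError(
                    f"spectra samples absent from metadata: {sorted(extra)[:5]}")
    return meta, traits, spectra, genes
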