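"""File input/output: TSV genotype matrices, map tables, VCF, and npz containers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import CodingError, GeneticMap, GenotypeMatrix, InvalidInputError

__all__ = [
    "read_map_tsv",
    "write_map_tsv",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "save_panel_npz",
    "load_panel_npz",
]

_MAP_COLUMNS = ["marker_id", "chromosome", "position_cM"]


def read_map_tsv(path) -> GeneticMap:
    """Read a genetic map from TSV with header marker_id, chromosome, position_cM.

    Chromosome length is taken as the largest mapped position on the chromosome.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _MAP_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"map file {path} lacks required columns {missing}")
    lengths = df.groupby("chromosome", sort=False)["position_cM"].max()
    chromosomes = [(c, float(l)) for c, l in lengths.items()]
    loci = list(zip(df["marker_id"], df["chromosome"], df["position_cM"]))
    return GeneticMap.build(chromosomes, loci)


def write_map_tsv(gmap: GeneticMap, path) -> None:
    gmap.to_dataframe().to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path, gmap: GeneticMap) -> GenotypeMatrix:
    """Read a 0/2 matrix: header row of locus ids, first column the individual id.

    Columns are aligned to the map's locus order; every map locus must be present.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [l for l in gmap.locus_ids if l not in df.columns]
    if missing:
        raise InvalidInputError(f"genotype file lacks {len(missing)} mapped loci, e.g. {missing[:3]}")
    scores = df.loc[:, list(gmap.locus_ids)].to_numpy()
    return GenotypeMatrix(scores.astype(np.int16), gmap, tuple(str(i) for i in df.index))


def write_genotypes_tsv(X: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(X.scores, index=list(X.individual_ids), columns=list(X.gmap.locus_ids))
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t")


def read_genotypes_vcf(path, gmap: GeneticMap) -> GenotypeMatrix:
    """Read fully homozygous genotypes from a VCF.

    Only 0/0 and 1/1 calls are accepted (the reference allele is the VCF REF);
    a heterozygous or missing call raises a CodingError naming variant and line.
    Variants are matched to the map by their ID field.
    """
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    by_id: dict[str, np.ndarray] = {}
    for variant in vcf:
        # gt_types: 0=hom-ref, 1=het, 2=unknown/missing, 3=hom-alt
        gt = variant.gt_types
        bad = np.nonzero((gt == 1) | (gt == 2))[0]
        if bad.size:
            raise CodingError(
                f"variant {variant.ID or variant.POS} has a heterozygous or missing call "
                f"for line {samples[int(bad[0])]!r}; only homozygous material is supported"
            )
        by_id[str(variant.ID)] = np.where(gt == 0, 2, 0).astype(np.int16)
    missing = [l for l in gmap.locus_ids if str(l) not in by_id]
    if missing:
        raise InvalidInputError(f"VCF lacks {len(missing)} mapped loci, e.g. {missing[:3]}")
    scores = np.column_stack([by_id[str(l)] for l in gmap.locus_ids])
    return GenotypeMatrix(scores, gmap, samples)


def save_panel_npz(X: GenotypeMatrix, path) -> None:
    """Write genotypes plus map into one portable compressed container."""
    gmap = X.gmap
    np.savez_compressed(
        Path(path),
        scores=X.scores.astype(np.int16),
        individual_ids=np.array(X.individual_ids, dtype=object),
        chrom_ids=np.array(gmap.chrom_ids, dtype=object),
        chrom_lengths=gmap.chrom_lengths,
        locus_ids=np.array(gmap.locus_ids, dtype=object),
        locus_chrom=gmap.locus_chrom,
        locus_pos=gmap.locus_pos,
    )


def load_panel_npz(path) -> GenotypeMatrix:
    with np.load(Path(path), allow_pickle=True) as z:
        gmap = GeneticMap(
            chrom_ids=tuple(z["chrom_ids"]),
            chrom_lengths=z["chrom_lengths"],
            locus_ids=tuple(z["locus_ids"]),
            locus_chrom=z["locus_chrom"],
            locus_pos=z["locus_pos"],
        )
        return GenotypeMatrix(z["scores"], gmap, tuple(z["individual_ids"]))
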