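"""Data containers, file formats, locus filtering and run configuration.

Genotypes live in a rectangular individuals x loci matrix of alternate-allele
counts 0/1/2 with ``-1`` for missing, plus a per-individual metadata table
(group / elevational band, latitude, longitude, species, sex).  On disk the
matrix is either a minimal VCF (each RAD locus its own contig, nominal 1-based
positions, unphased GT, ``./.`` missing) or a TSV table; per-locus haplotype
alignments are plain multi-FASTA.  All readers and writers round-trip.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("coalabc")

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "LocusAlignment",
    "LocusAlignmentSet",
    "RunConfig",
    "read_genotypes",
    "write_genotypes",
    "read_alignments",
    "write_alignments",
    "filter_loci",
    "write_manifest",
]


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci, codes {0, 1, 2, -1=missing}."""

    genotypes: np.ndarray
    individuals: list[str]
    loci: list[str]
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        n_ind, n_loc = self.genotypes.shape
        if len(self.individuals) != n_ind or len(self.loci) != n_loc:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.individuals)) != n_ind or len(set(self.loci)) != n_loc:
            raise ValueError("individual and locus ids must be unique")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.genotypes[bad])}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-locus fraction of missing genotype calls."""
        return (self.genotypes == MISSING).mean(axis=0)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus ``(alt_copies, called_copies)`` from non-missing calls."""
        called = self.genotypes != MISSING
        alt = np.where(called, self.genotypes, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def allele_frequencies(self) -> np.ndarray:
        """Per-locus alternate-allele frequency (NaN where all calls missing)."""
        alt, called = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, alt / called, np.nan)

    def subset_individuals(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        meta = self.metadata.iloc[idx] if self.metadata is not None else None
        return GenotypeMatrix(
            self.genotypes[idx],
            [self.individuals[i] for i in idx],
            list(self.loci),
            meta,
        )

    def subset_loci(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.genotypes[:, idx],
            list(self.individuals),
            [self.loci[i] for i in idx],
            self.metadata,
        )


@dataclass
class LocusAlignment:
    """Equal-length haplotype sequences for one RAD locus."""

    locus_id: str
    names: list[str]
    sequences: list[str]
    individual_of_origin: list[int] | None = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths in locus {self.locus_id}")
        alphabet = set("ACGTN-")
        for s in self.sequences:
            extra = set(s.upper()) - alphabet
            if extra:
                raise ValueError(f"invalid characters {extra} in locus {self.locus_id}")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    def as_array(self) -> np.ndarray:
        return np.array([list(s.upper()) for s in self.sequences])


@dataclass
class LocusAlignmentSet:
    loci: list[LocusAlignment]

    def __iter__(self):
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def total_length(self) -> int:
        return sum(a.length for a in self.loci)


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from ``vcf`` or ``tsv`` (guessed from suffix).

    VCF parsing goes through :mod:`pysam`; unphased GT fields map to 0/1/2
    alt-allele counts and ``./.`` to missing.  Multi-allelic records are
    dropped, with the count reported as a warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in {".vcf", ".gz", ".bcf"} else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format: {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        individuals = list(vf.header.samples)
        loci, rows = [], []
        n_multi = 0
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multi += 1
                continue
            row = np.empty(len(individuals), dtype=np.int8)
            for i, sample in enumerate(individuals):
                gt = rec.samples[sample]["GT"]
                if gt is None or any(a is None for a in gt):
                    row[i] = MISSING
                else:
                    row[i] = sum(1 for a in gt if a == 1)
            loci.append(rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}")
            rows.append(row)
    if n_multi:
        warnings.warn(f"dropped {n_multi} multi-allelic record(s)", UserWarning, stacklevel=2)
    geno = np.array(rows, dtype=np.int8).T if rows else np.empty((len(individuals), 0), np.int8)
    return GenotypeMatrix(geno, individuals, loci)


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=object)
    geno = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    geno = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
    return GenotypeMatrix(geno, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_genotypes(g: GenotypeMatrix, path: str | Path, fmt: str | None = None) -> None:
    """Write a genotype matrix as minimal VCF or TSV."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "vcf":
        _write_vcf(g, path)
    elif fmt == "tsv":
        df = pd.DataFrame(g.genotypes.astype(object), index=g.individuals, columns=g.loci)
        df = df.mask(df == MISSING, other=pd.NA)
        df.to_csv(path, sep="\t", na_rep="NA", index_label="individual")
    else:
        raise ValueError(f"unknown genotype format: {fmt!r}")


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    # Nominal coordinates: each locus is its own contig at position 1 (denovo
    # RAD loci have no reference genome).  REF=A, ALT=T are placeholders for
    # the anonymous ancestral/derived alleles.
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=coalabc\n")
        for locus in g.loci:
            fh.write(f"##contig=<ID={locus},length=2>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.individuals) + "\n")
        for j, locus in enumerate(g.loci):
            calls = "\t".join(gt_codes[int(v)] for v in g.genotypes[:, j])
            fh.write(f"{locus}\t1\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


# ---------------------------------------------------------------------------
# alignment I/O (multi-FASTA per locus via Biopython)
# ---------------------------------------------------------------------------

def write_alignments(aln: LocusAlignmentSet, directory: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for locus in aln:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in zip(locus.names, locus.sequences)
        ]
        SeqIO.write(records, directory / f"{locus.locus_id}.fasta", "fasta")


def read_alignments(directory: str | Path) -> LocusAlignmentSet:
    from Bio import SeqIO

    directory = Path(directory)
    loci = []
    for path in sorted(directory.glob("*.fasta")):
        names, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq).upper())
        loci.append(LocusAlignment(locus_id=path.stem, names=names, sequences=seqs))
    if not loci:
        raise FileNotFoundError(f"no .fasta files under {directory}")
    return LocusAlignmentSet(loci=loci)


# ---------------------------------------------------------------------------
# locus filtering
# ---------------------------------------------------------------------------

def filter_loci(
    g: GenotypeMatrix,
    max_missing: float = 0.2,
    locus_groups: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Apply the standard RAD-SNP filter: drop loci with more than
    ``max_missing`` missing data, then keep a single SNP chosen uniformly at
    random within each RAD-locus group (``locus_groups`` maps SNP id ->
    RAD-locus id; ungrouped SNPs pass through)."""
    keep = g.missing_fraction() <= max_missing
    out = g.subset_loci(keep)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_loci: dropped %d locus/loci above %.0f%% missing", n_dropped, 100 * max_missing)
    if locus_groups:
        if rng is None:
            raise ValueError("one-SNP-per-locus thinning needs an rng")
        by_group: dict[str, list[int]] = {}
        singles: list[int] = []
        for j, snp in enumerate(out.loci):
            grp = locus_groups.get(snp)
            if grp is None:
                singles.append(j)
            else:
                by_group.setdefault(grp, []).append(j)
        chosen = singles + [members[rng.integers(len(members))] for members in
                            (by_group[k] for k in sorted(by_group))]
        out = out.subset_loci(np.sort(np.array(chosen, dtype=np.int64)))
    if out.n_loci == 0:
        raise ValueError("no loci survive filtering")
    return out


# ---------------------------------------------------------------------------
# run configuration & manifests
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable knobs shared by the CLI commands."""

    seed: int = 1
    n_sims_per_model: int = 20000
    n_accept: int = 500
    max_missing: float = 0.2
    n_fst_permutations: int = 10000
    n_mantel_permutations: int = 999
    prior_bounds: dict = field(
        default_factory=lambda: {
            "Nc": [100.0, 200000.0],
            "NA": [100.0, 30000.0],
            "N": [10000.0, 200000.0],
            "TEXP1": [10000.0, 40000.0],
            "TEXP2": [110000.0, 130000.0],
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing < 1.0:
            raise ValueError("max_missing must be in [0, 1)")
        if self.n_accept < 1 or self.n_sims_per_model < 1:
            raise ValueError("counts must be positive")
        for name, (lo, hi) in self.prior_bounds.items():
            if not (0 < lo < hi):
                raise ValueError(f"bad prior bounds for {name}: {(lo, hi)}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def write_manifest(path: str | Path, *, command: str, seed: int, inputs: dict, outputs: list[str]) -> None:
    """Machine-readable record of one CLI run."""
    from . import __version__

    manifest = {
        "tool": "coalabc",
        "version": __version__,
        "command": command,
        "seed": seed,
        "inputs": inputs,
        "outputs": outputs,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
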