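"""File formats and run configuration.

Fragment files are tab-separated text, one read per line::

    individual_id <TAB> read_id <TAB> site:allele [<TAB> site:allele ...]

with 0-based ascending window site indices and alleles in {0, 1}. Sites
lists and phased haplotypes travel as VCF 4.x (biallelic SNPs, phased GT
with '|', optional log10-scaled GL triples). Every file written carries a
header recording the package version, a config hash, and the seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from . import __version__
from .types import HaplotypePair, PhyloTree, Read, ReadSets

__all__ = [
    "RunConfig",
    "read_fragment_file",
    "write_fragment_file",
    "read_sites_vcf",
    "read_phased_vcf",
    "write_phased_vcf",
    "write_tree_tsv",
    "write_tree_newick",
    "FragmentFormatError",
]


class FragmentFormatError(ValueError):
    """Malformed fragment file (reported with the offending line number)."""


@dataclass(frozen=True)
class RunConfig:
    """Phasing pipeline parameters."""

    window_length: int = 5
    error_rate: float = 0.02
    alpha1: float = 2.0
    alpha2: float = 1.2
    d_star: int | None = None
    partition_method: str = "pphs2"
    seed: int = 0
    max_enumeration_m: int = 12
    recode_major_allele: bool = True

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must satisfy 0 <= eps < 0.5")
        if self.partition_method not in ("pphs2", "pphs3"):
            raise ValueError("partition_method must be pphs2 or pphs3")
        if self.alpha1 <= 1 or self.alpha2 <= 1:
            raise ValueError("Dirichlet weights must be > 1")

    def hash(self) -> str:
        text = ";".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Flat key=value config file; explicit keyword overrides win."""
        values: dict = {}
        casts = {f: t for f, t in cls.__annotations__.items()}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected key=value")
            key, val = (x.strip() for x in line.split("=", 1))
            if key not in casts:
                raise ValueError(f"{path}:{ln}: unknown key {key!r}")
            if key == "partition_method":
                values[key] = val
            elif key == "d_star":
                values[key] = None if val.lower() == "none" else int(val)
            elif key == "recode_major_allele":
                values[key] = val.lower() in ("1", "true", "yes")
            elif key in ("window_length", "seed", "max_enumeration_m"):
                values[key] = int(val)
            else:
                values[key] = float(val)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def _header_line(kind: str, config: RunConfig | None, seed: int | None, extra: str = "") -> str:
    cfg = config.hash() if config is not None else "none"
    s = seed if seed is not None else (config.seed if config is not None else 0)
    return f"#pphs {kind} version={__version__} config={cfg} seed={s}{extra}"


# ---------------------------------------------------------------------------
# fragment files
# ---------------------------------------------------------------------------


def write_fragment_file(
    path: str | Path,
    reads: ReadSets,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    lines = [_header_line("fragments", config, seed, f" m={reads.m}")]
    for r in reads.to_reads():
        obs = "\t".join(f"{s}:{a}" for s, a in r.observations)
        lines.append(f"{r.individual_id}\t{r.read_id}\t{obs}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fragment_file(path: str | Path, m_snps: int | None = None) -> ReadSets:
    reads: list[Read] = []
    header_m = None
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if line.startswith("#"):
            for tok in line.split():
                if tok.startswith("m="):
                    header_m = int(tok[2:])
            continue
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 3:
            raise FragmentFormatError(f"{path}:{ln}: expected at least 3 columns")
        ind, rid, *tokens = cols
        obs = []
        for tok in tokens:
            try:
                site_s, allele_s = tok.split(":")
                site, allele = int(site_s), int(allele_s)
            except ValueError as e:
                raise FragmentFormatError(f"{path}:{ln}: bad token {tok!r}") from e
            if allele not in (0, 1):
                raise FragmentFormatError(f"{path}:{ln}: allele must be 0 or 1")
            obs.append((site, allele))
        try:
            reads.append(Read(ind, rid, tuple(obs)))
        except ValueError as e:
            raise FragmentFormatError(f"{path}:{ln}: {e}") from e
    if m_snps is None:
        m_snps = header_m
    if m_snps is None:
        m_snps = 1 + max((s for r in reads for s, _ in r.observations), default=-1)
        if m_snps == 0:
            m_snps = 1
    return ReadSets.from_reads(reads, m_snps)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _vcf_header(
    chrom: str,
    region_length: int,
    samples: Sequence[str],
    with_gl: bool,
    config: RunConfig | None,
    seed: int | None,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.contigs.add(chrom, length=max(region_length, 1))
    header.formats.add("GT", 1, "String", "Genotype")
    if with_gl:
        header.formats.add(
            "GL", "G", "Float", "Log10 genotype likelihoods for 0/0, 0/1, 1/1"
        )
    header.add_line(f"##pphs_version={__version__}")
    header.add_line(f"##pphs_config={config.hash() if config else 'none'}")
    header.add_line(f"##pphs_seed={seed if seed is not None else (config.seed if config else 0)}")
    for s in samples:
        header.add_sample(s)
    return header


def write_phased_vcf(
    path: str | Path,
    positions: Sequence[int],
    pairs: Sequence[HaplotypePair],
    chrom: str = "1",
    region_length: int | None = None,
    gl: np.ndarray | None = None,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    """Phased biallelic SNPs, REF=A ALT=G placeholders, GT '|'-separated.

    ``gl`` is an optional (n, m, 3) array of linear likelihoods over
    {(0,0), (0,1), (1,1)}; written log10-scaled in the GL field.
    """
    m = len(positions)
    if any(len(p) != m for p in pairs):
        raise ValueError("haplotype length must match the number of sites")
    region_length = region_length or (max(positions) if m else 1)
    samples = [p.individual_id for p in pairs]
    header = _vcf_header(chrom, region_length, samples, gl is not None, config, seed)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, pos in enumerate(positions):
            rec = vcf.new_record(contig=chrom, start=pos - 1, alleles=("A", "G"))
            rec.id = f"snp{j}"
            for i, pair in enumerate(pairs):
                rec.samples[i]["GT"] = (pair.h1[j], pair.h2[j])
                rec.samples[i].phased = True
                if gl is not None:
                    rec.samples[i]["GL"] = tuple(
                        float(np.log10(max(x, 1e-300))) for x in gl[i, j]
                    )
            vcf.write(rec)


def read_sites_vcf(path: str | Path) -> tuple[str, list[int]]:
    """Chromosome name and 1-based SNP positions of a biallelic sites VCF."""
    positions = []
    chrom = "1"
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"{path}: site at POS {rec.pos} is not biallelic")
            chrom = rec.chrom
            positions.append(rec.pos)
    return chrom, positions


def read_phased_vcf(path: str | Path) -> tuple[list[int], list[HaplotypePair]]:
    """Phased haplotypes from a scaffold/truth VCF; unphased records are errors."""
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        haps: dict[str, tuple[list[int], list[int]]] = {s: ([], []) for s in samples}
        positions = []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"{path}: record at POS {rec.pos} is not biallelic")
            positions.append(rec.pos)
            for s in samples:
                call = rec.samples[s]
                gt = call["GT"]
                if gt is None or None in gt or len(gt) != 2:
                    raise ValueError(f"{path}: missing GT at POS {rec.pos} for {s}")
                if not call.phased:
                    raise ValueError(
                        f"{path}: unphased genotype ('/') at POS {rec.pos} for {s}"
                    )
                haps[s][0].append(int(gt[0]))
                haps[s][1].append(int(gt[1]))
    pairs = [HaplotypePair(s, tuple(haps[s][0]), tuple(haps[s][1])) for s in samples]
    return positions, pairs


# ---------------------------------------------------------------------------
# tree dumps and reports
# ---------------------------------------------------------------------------


def write_tree_tsv(
    path: str | Path, tree: PhyloTree, config: RunConfig | None = None, seed: int | None = None
) -> None:
    lines = [_header_line("tree", config, seed)]
    lines.append("node\tparent\tsnp\thaplotype\tp_v")
    for row in tree.to_table():
        lines.append(
            f"{row['node']}\t{row['parent']}\t{row['snp']}\t{row['haplotype']}\t{row['p_v']:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_tree_newick(
    path: str | Path, tree: PhyloTree, config: RunConfig | None = None, seed: int | None = None
) -> None:
    Path(path).write_text(_header_line("newick", config, seed) + "\n" + tree.to_newick() + "\n")


def write_evaluation_tsv(
    path: str | Path,
    rows: Sequence[dict],
    config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    if not rows:
        Path(path).write_text(_header_line("evaluation", config, seed) + "\n")
        return
    cols = list(rows[0])
    lines = [_header_line("evaluation", config, seed), "\t".join(cols)]
    for r in rows:
        lines.append("\t".join(str(r[c]) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")
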