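"""Seeded synthetic genome sets with machine-readable ground truth.

The generator emits everything the analysis stages consume — multi-replicon
FASTA, CDS annotations with bcs/GGDEF/EAL products and domains, insertion
sequence and prophage element rows, a genome manifest, a gene-cluster
membership table, a plasmid catalog with per-plasmid CDS product sets and a
mobility-typing table — together with an exhaustive ``TruthSet`` recording
every planted value, so parameter recovery can be asserted exactly.

The default configuration echoes the shape of the curated study dataset:
18 genomes across 10 species labels (3 singleton species); twelve plasmid
families of sizes 7, 6, three 3s, and seven 2s (36 plasmids over 13 host
genomes), with the size-7 family planted as a mosaic (30% shared module)
and the rest as mutated backbones split between highly and moderately
conserved rates; one genome whose bcsA/bcsZ never co-localize; three
genomes with dispersed multi-copy bcsA; 14 genomes with GGDEF and EAL
genes inside the 50-kb anchor window and 4 lacking both; per-genome IS
counts drawn in [50, 181] and prophage region lengths in [10080, 70900].
Chromosomes default to 2 Mb — enough to hold the planted element densities
at realistic occupancy while keeping generated sets light.

Randomness comes exclusively from ``numpy.random.default_rng`` (PCG64)
streams spawned from a single seed, so identical (config, seed) pairs give
byte-identical outputs across runs and platforms.  Backbone mutation is
substitution-only (no indels), keeping exact k-mer-Jaccard oracles simple.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .manifest import GenomeManifest, GenomeRecord
from .plasmids import classify_conservation, MOSAIC_LIKE, SINGLETON

__all__ = [
    "PlasmidFamilySpec",
    "BcsArchSpec",
    "ISSpec",
    "ProphageSpec",
    "PangenomeSpec",
    "SynthConfig",
    "SynthPlasmid",
    "TruthSet",
    "SyntheticGenomeSet",
    "default_config",
    "generate_genome_set",
    "mutate_backbone",
    "plant_mosaic_family",
    "random_sequence",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

_ENC = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _ENC[_b] = _c


class InfeasibleConfigError(ValueError):
    """The requested planted elements cannot fit the genome."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PlasmidFamilySpec:
    name: str
    mode: str  # "backbone" | "mosaic"
    n_members: int
    backbone_length: int  # backbone length (backbone mode) or module length (mosaic)
    mutation_rate: float = 0.005
    module_fraction: float = 0.3
    hosts: tuple[str, ...] | None = None  # genome accessions, len == n_members

    def __post_init__(self) -> None:
        if self.mode not in ("backbone", "mosaic"):
            raise ValueError(f"unknown family mode {self.mode!r}")
        if not (0.0 <= self.mutation_rate <= 0.5):
            raise ValueError("mutation_rate must be in [0, 0.5]")
        if self.mode == "mosaic" and not (0.0 < self.module_fraction < 1.0):
            raise ValueError("module_fraction must be in (0, 1)")
        if self.backbone_length <= 0 or self.n_members < 1:
            raise ValueError("lengths and member counts must be positive")

    @property
    def expected_category(self) -> str:
        if self.n_members == 1:
            return SINGLETON
        if self.mode == "mosaic":
            return MOSAIC_LIKE
        # two members mutated independently at rate r diverge at ~2r(1-r)
        return classify_conservation(2 * self.mutation_rate * (1 - self.mutation_rate))


@dataclass(frozen=True)
class BcsArchSpec:
    qualifies: bool = True  # bcsA and bcsZ co-localize on one contig
    bcsA_copies: int = 2
    dispersed: bool = False  # bcsA copies on more than one contig
    ggdef_in_window: bool = True
    eal_in_window: bool = True


@dataclass(frozen=True)
class ISSpec:
    count_range: tuple[int, int] = (50, 181)
    length_range: tuple[int, int] = (700, 2500)


@dataclass(frozen=True)
class ProphageSpec:
    count_range: tuple[int, int] = (1, 4)
    length_range: tuple[int, int] = (10_080, 70_900)


@dataclass(frozen=True)
class PangenomeSpec:
    n_core: int = 150
    n_accessory: int = 450
    singleton_range: tuple[int, int] = (5, 40)


@dataclass(frozen=True)
class SynthConfig:
    n_genomes: int = 18
    chromosome_length_bp: int = 2_000_000
    alt_contig_length_bp: int = 60_000
    plasmid_families: tuple[PlasmidFamilySpec, ...] = ()
    bcs_specs: tuple[BcsArchSpec, ...] = ()
    is_spec: ISSpec = ISSpec()
    prophage_spec: ProphageSpec = ProphageSpec()
    pangenome_spec: PangenomeSpec = PangenomeSpec()
    seed: int = 0


def _accession(i: int) -> str:
    return f"GCF_{700000000 + i}.1"


#: species layout echoing the reference dataset: 10 labels, 3 singleton species
_SPECIES_LAYOUT = (3, 2, 2, 2, 2, 2, 2, 1, 1, 1)


def _default_species(n_genomes: int) -> list[str]:
    labels = []
    letter = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    for count in _SPECIES_LAYOUT:
        name = f"K. synthetica {next(letter)}"
        labels.extend([name] * count)
    while len(labels) < n_genomes:
        labels.append(f"K. synthetica {next(letter)}")
    return labels[:n_genomes]


def default_config(seed: int = 0) -> SynthConfig:
    """The default 18-genome study-shaped configuration."""
    acc = [_accession(i + 1) for i in range(18)]
    g = lambda *idx: tuple(acc[i - 1] for i in idx)  # noqa: E731 - 1-based picks
    fams = (
        PlasmidFamilySpec("fam01", "mosaic", 7, 12_000, module_fraction=0.3,
                          hosts=g(1, 2, 4, 6, 8, 10, 12)),
        PlasmidFamilySpec("fam02", "backbone", 6, 35_000, mutation_rate=0.005,
                          hosts=g(1, 2, 3, 4, 6, 8)),
        PlasmidFamilySpec("fam03", "backbone", 3, 25_000, mutation_rate=0.005,
                          hosts=g(4, 5, 6)),
        PlasmidFamilySpec("fam04", "backbone", 3, 18_000, mutation_rate=0.005,
                          hosts=g(1, 2, 3)),
        PlasmidFamilySpec("fam05", "backbone", 3, 22_000, mutation_rate=0.015,
                          hosts=g(1, 2, 3)),
        PlasmidFamilySpec("fam06", "backbone", 2, 15_000, mutation_rate=0.005,
                          hosts=g(8, 10)),
        PlasmidFamilySpec("fam07", "backbone", 2, 12_000, mutation_rate=0.005,
                          hosts=g(4, 5)),
        PlasmidFamilySpec("fam08", "backbone", 2, 20_000, mutation_rate=0.015,
                          hosts=g(6, 7)),
        PlasmidFamilySpec("fam09", "backbone", 2, 16_000, mutation_rate=0.005,
                          hosts=g(8, 9)),
        PlasmidFamilySpec("fam10", "backbone", 2, 14_000, mutation_rate=0.015,
                          hosts=g(10, 11)),
        PlasmidFamilySpec("fam11", "backbone", 2, 10_000, mutation_rate=0.015,
                          hosts=g(12, 13)),
        PlasmidFamilySpec("fam12", "backbone", 2, 28_000, mutation_rate=0.015,
                          hosts=g(1, 2)),
    )
    # genome 8 mirrors the one non-qualifying genome; 6, 7, 8 carry dispersed
    # multi-copy bcsA; 6, 7, 8, 17 lack both GGDEF and EAL within the window
    bcs = []
    for i in range(1, 19):
        dispersed = i in (6, 7, 8)
        bcs.append(
            BcsArchSpec(
                qualifies=i != 8,
                bcsA_copies=3 if dispersed else 2,
                dispersed=dispersed,
                ggdef_in_window=i not in (6, 7, 8, 17),
                eal_in_window=i not in (6, 7, 8, 17),
            )
        )
    return SynthConfig(plasmid_families=fams, bcs_specs=tuple(bcs), seed=seed)


# ---------------------------------------------------------------------------
# sequence primitives


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform-ACGT random nucleotide sequence."""
    if length < 0:
        raise ValueError("length must be non-negative")
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate_backbone(
    backbone: str, rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    """Apply i.i.d. substitutions (to a uniformly chosen *different* base).

    Returns the mutated sequence and the realized substitution count.
    """
    if not (0.0 <= rate <= 0.5):
        raise ValueError("rate must be in [0, 0.5]")
    codes = _ENC[np.frombuffer(backbone.encode("ascii"), dtype=np.uint8)].copy()
    if (codes == 255).any():
        raise ValueError("backbone must contain only ACGT")
    mask = rng.random(codes.size) < rate
    n_sub = int(mask.sum())
    if n_sub:
        shift = rng.integers(1, 4, size=n_sub).astype(np.uint8)
        codes[mask] = (codes[mask] + shift) % 4
    return _BASES[codes].tobytes().decode(), n_sub


def plant_mosaic_family(
    module: str,
    n_members: int,
    module_fraction: float,
    rng: np.random.Generator,
) -> list[str]:
    """Members sharing one module embedded in independent random filler.

    Each member has total length ``len(module) / module_fraction`` with the
    module at a random offset, so pairwise k-mer overlap is dominated by the
    shared module (mosaic-like relationships).
    """
    if not (0.0 < module_fraction < 1.0):
        raise ValueError("module_fraction must be in (0, 1)")
    total = int(round(len(module) / module_fraction))
    filler = total - len(module)
    members = []
    for _ in range(n_members):
        left = int(rng.integers(0, filler + 1))
        members.append(
            random_sequence(left, rng) + module + random_sequence(filler - left, rng)
        )
    return members


def _place_intervals(
    lengths: Sequence[int],
    contig_length: int,
    occupied: list[tuple[int, int]],
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> list[tuple[int, int]]:
    """Place non-overlapping 1-based closed intervals by rejection sampling."""
    if sum(lengths) + sum(e - s + 1 for s, e in occupied) > 0.8 * contig_length:
        raise InfeasibleConfigError(
            "planted elements exceed 80% of contig length; reduce counts/lengths"
        )
    occ = list(occupied)
    placed = []
    for ln in sorted(lengths, reverse=True):
        if ln > contig_length:
            raise InfeasibleConfigError(f"element of length {ln} exceeds contig")
        for _ in range(max_tries):
            s = int(rng.integers(1, contig_length - ln + 2))
            e = s + ln - 1
            if not any(s <= oe and e >= os_ for os_, oe in occ):
                occ.append((s, e))
                placed.append((s, e))
                break
        else:
            raise InfeasibleConfigError("could not place element without overlap")
    return sorted(placed)


def _mutate_protein(base: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(base.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < rate
    if mask.any():
        arr[mask] = _AA[rng.integers(0, _AA.size, size=int(mask.sum()))]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# products / CDS layout

_BCS_LAYOUT = {
    # offsets relative to the bcs block start: (start, end, gene, product)
    "bcsA": (0, 2204, "cellulose synthase catalytic subunit"),
    "bcsB": (2300, 4601, "cellulose synthase cyclic di-GMP-binding regulatory subunit"),
    "bcsC": (4700, 8000, "cellulose synthase operon protein C"),
    "bcsD": (8100, 8597, "cellulose synthase operon protein D"),
    "bcsZ": (8700, 9797, "endoglucanase BcsZ"),
    "bcsQ": (9900, 10697, "cellulose synthesis protein BcsQ"),
}
_BCSA_EXTRA_OFFSETS = (15_000, 20_000)  # additional same-contig bcsA copies
_BCSA_LEN = 2204
_GGDEF_IN, _GGDEF_OUT = 10_000, 120_000  # offsets past the anchored span end
_EAL_IN, _EAL_OUT = 20_000, 140_000
_DOMAIN_GENE_LEN = 1500
_DUAL_DOMAIN_OFFSET = 200_000


@dataclass(frozen=True)
class SynthPlasmid:
    plasmid_id: str
    host: str
    family: str
    sequence: str
    expected_category: str


@dataclass(frozen=True)
class TruthSet:
    """Exhaustive record of every planted value, keyed for recovery tests."""

    seed: int
    genomes: dict
    families: dict
    plasmids: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "genomes": self.genomes,
                "families": self.families,
                "plasmids": self.plasmids,
            },
            sort_keys=True,
            indent=2,
        )


@dataclass
class SyntheticGenomeSet:
    config: SynthConfig
    manifest: GenomeManifest
    contigs: dict[str, dict[str, str]]  # genome -> contig -> sequence
    contig_lengths: dict[str, int]
    plasmids: list[SynthPlasmid]
    features: pd.DataFrame  # CDS table (richness schema, incl. protein)
    elements: pd.DataFrame  # IS + prophage rows (burden schema)
    membership: pd.DataFrame  # gene cluster x genome incidence
    products: dict[str, tuple[str, ...]]  # plasmid_id -> CDS product set
    mobility: pd.DataFrame
    truth: TruthSet

    def plasmid_sequences(self) -> dict[str, str]:
        return {p.plasmid_id: p.sequence for p in self.plasmids}

    def write(self, outdir: str | Path) -> None:
        """Write FASTA/GFF3/TSV/JSON artifacts; deterministic byte-for-byte."""
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        out = Path(outdir)
        (out / "genomes").mkdir(parents=True, exist_ok=True)
        (out / "annotations").mkdir(parents=True, exist_ok=True)
        for acc in self.manifest.accessions:
            recs = [
                SeqRecord(Seq(seq), id=contig, description="")
                for contig, seq in sorted(self.contigs[acc].items())
            ]
            SeqIO.write(recs, str(out / "genomes" / f"{acc}.fasta"), "fasta")
            self._write_gff(out / "annotations" / f"{acc}.gff3", acc)
        plasmid_recs = [
            SeqRecord(Seq(p.sequence), id=p.plasmid_id, description="")
            for p in self.plasmids
        ]
        SeqIO.write(plasmid_recs, str(out / "plasmids.fasta"), "fasta")
        self.manifest.to_frame().to_csv(out / "manifest.tsv", sep="\t", index=False)
        self.elements.to_csv(out / "elements.tsv", sep="\t", index=False)
        self.membership.to_csv(out / "membership.tsv", sep="\t")
        self.mobility.to_csv(out / "mobility.tsv", sep="\t", index=False)
        prod_rows = [
            {"plasmid_id": pid, "product": prod}
            for pid in sorted(self.products)
            for prod in self.products[pid]
        ]
        pd.DataFrame(prod_rows).to_csv(out / "plasmid_products.tsv", sep="\t", index=False)
        (out / "truth.json").write_text(self.truth.to_json() + "\n")

    def _write_gff(self, path: Path, acc: str) -> None:
        lines = ["##gff-version 3"]
        feats = self.features[self.features["genome"] == acc]
        for i, row in enumerate(feats.itertuples(index=False)):
            attrs = [f"ID=cds-{acc}-{i + 1}"]
            if row.gene:
                attrs.append(f"gene={row.gene}")
            if row.product:
                attrs.append(f"product={row.product}")
            if row.domains:
                attrs.append(f"domain={row.domains}")
            if isinstance(row.protein, str) and row.protein:
                attrs.append(f"translation={row.protein}")
            lines.append(
                f"{row.contig}\tkomagen-synth\tCDS\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t0\t{';'.join(attrs)}"
            )
        elems = self.elements[self.elements["genome"] == acc]
        for i, row in enumerate(elems.itertuples(index=False)):
            ftype = (
                "mobile_genetic_element" if row.element_type == "IS" else "sequence_feature"
            )
            lines.append(
                f"{row.contig}\tkomagen-synth\t{ftype}\t{row.start}\t{row.end}\t.\t+\t.\t"
                f"ID=elem-{acc}-{i + 1};element_type={row.element_type};label={row.label}"
            )
        path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# generation


def _plant_bcs(
    acc: str,
    spec: BcsArchSpec,
    chrom: str,
    alt: str,
    zctg: str,
    chrom_len: int,
    alt_len: int,
    proteins: Mapping[str, str],
) -> tuple[list[dict], dict, list[tuple[int, int]]]:
    """CDS rows + truth + occupied chromosome intervals for one bcs locus.

    Non-qualifying genomes get bcsZ on a dedicated contig (``zctg``) so no
    contig carries both bcsA and bcsZ, even when extra dispersed bcsA copies
    occupy the alt contig.
    """
    p0 = chrom_len // 4
    rows: list[dict] = []
    occupied: list[tuple[int, int]] = []

    def add(contig, start, end, gene, product, domains="", protein=None):
        if contig == chrom and end > chrom_len:
            raise InfeasibleConfigError(
                f"bcs placement exceeds chromosome length for {acc}"
            )
        if contig in (alt, zctg) and end > alt_len:
            raise InfeasibleConfigError(f"bcs placement exceeds alt contig for {acc}")
        rows.append(
            {
                "genome": acc, "contig": contig, "start": start, "end": end,
                "strand": "+", "gene": gene, "product": product,
                "domains": domains, "protein": protein,
            }
        )
        if contig == chrom:
            occupied.append((start, end))

    for target, (off_s, off_e, product) in _BCS_LAYOUT.items():
        if target == "bcsZ" and not spec.qualifies:
            add(zctg, 20_000, 21_097, "bcsZ", product, protein=proteins.get("bcsZ"))
            continue
        add(chrom, p0 + off_s, p0 + off_e, target, product, protein=proteins.get(target))

    n_extra = max(0, spec.bcsA_copies - 1)
    prodA = _BCS_LAYOUT["bcsA"][2]
    if spec.dispersed:
        for c, off in zip(range(n_extra), (5_000, 10_000)):
            add(alt, off, off + _BCSA_LEN, "bcsA", prodA, protein=proteins.get("bcsA"))
    else:
        for c in range(n_extra):
            off = _BCSA_EXTRA_OFFSETS[c]
            add(chrom, p0 + off, p0 + off + _BCSA_LEN, "bcsA", prodA,
                protein=proteins.get("bcsA"))

    anchor_rows = [r for r in rows if r["contig"] == chrom]
    span = (min(r["start"] for r in anchor_rows), max(r["end"] for r in anchor_rows))

    gg_off = _GGDEF_IN if spec.ggdef_in_window else _GGDEF_OUT
    add(chrom, span[1] + gg_off, span[1] + gg_off + _DOMAIN_GENE_LEN,
        "", "diguanylate cyclase", domains="GGDEF")
    eal_off = _EAL_IN if spec.eal_in_window else _EAL_OUT
    add(chrom, span[1] + eal_off, span[1] + eal_off + _DOMAIN_GENE_LEN,
        "", "c-di-GMP phosphodiesterase", domains="EAL")
    # a distant dual-domain protein, outside every window by construction
    add(chrom, p0 + _DUAL_DOMAIN_OFFSET, p0 + _DUAL_DOMAIN_OFFSET + _DOMAIN_GENE_LEN,
        "", "bifunctional diguanylate cyclase/phosphodiesterase", domains="GGDEF,EAL")

    truth = {
        "qualifies": spec.qualifies,
        "anchor_contig": chrom if spec.qualifies else None,
        "anchor_span": list(span) if spec.qualifies else None,
        "bcsA_copies": spec.bcsA_copies,
        "bcsA_dispersed": spec.dispersed,
        "bcsQ_on_anchor": spec.qualifies,  # bcsQ is always planted on the chromosome
        "ggdef_in_window": spec.ggdef_in_window,
        "eal_in_window": spec.eal_in_window,
    }
    return rows, truth, occupied


def _family_products(
    fam: PlasmidFamilySpec, member_ids: Sequence[str], rng: np.random.Generator
) -> dict[str, tuple[str, ...]]:
    shared = [f"{fam.name} backbone protein {i + 1}" for i in range(14)]
    out = {}
    for pid in member_ids:
        if fam.mode == "mosaic":
            uniq = [f"{pid.split('|', 1)[1]} cargo orf {j + 1}" for j in range(10)]
            out[pid] = tuple(shared[:6] + uniq)
        else:
            drop = int(rng.integers(0, 3))
            kept = shared[: len(shared) - drop]
            out[pid] = tuple(kept)
    return out


def generate_genome_set(
    config: SynthConfig | None = None, seed: int | None = None
) -> SyntheticGenomeSet:
    """Generate a full synthetic genome set with ground truth.

    ``seed`` overrides ``config.seed`` when given.  All infeasibility checks
    run before any artifact is assembled, and identical (config, seed) pairs
    produce identical output (including byte-identical files from
    :meth:`SyntheticGenomeSet.write`).
    """
    if config is None:
        config = default_config()
    if seed is not None:
        config = SynthConfig(**{**asdict_shallow(config), "seed": seed})
    n = config.n_genomes
    if n < 1:
        raise InfeasibleConfigError("need at least one genome")
    bcs_specs = config.bcs_specs or tuple(BcsArchSpec() for _ in range(n))
    if len(bcs_specs) != n:
        raise InfeasibleConfigError("bcs_specs length must equal n_genomes")

    accs = [_accession(i + 1) for i in range(n)]
    species = _default_species(n)
    for fam in config.plasmid_families:
        if fam.hosts is not None:
            if len(fam.hosts) != fam.n_members:
                raise InfeasibleConfigError(
                    f"family {fam.name}: hosts length != n_members"
                )
            unknown = set(fam.hosts) - set(accs)
            if unknown:
                raise InfeasibleConfigError(
                    f"family {fam.name}: unknown host accession(s) {sorted(unknown)}"
                )

    ss = np.random.SeedSequence(config.seed)
    rng_chrom, rng_plasmid, rng_protein, rng_elem, rng_pan, rng_mob = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    # --- target proteins: one base per target, genome-specific variants
    targets = list(_BCS_LAYOUT)
    base_proteins = {t: _AA[rng_protein.integers(0, 20, 280)].tobytes().decode() for t in targets}
    per_genome_proteins = {
        acc: {t: _mutate_protein(base_proteins[t], 0.02, rng_protein) for t in targets}
        for acc in accs
    }

    # --- contigs, bcs loci, elements
    contigs: dict[str, dict[str, str]] = {}
    contig_lengths: dict[str, int] = {}
    feature_rows: list[dict] = []
    element_rows: list[dict] = []
    genome_truth: dict[str, dict] = {}
    chrom_len = config.chromosome_length_bp
    alt_len = config.alt_contig_length_bp

    is_lo, is_hi = config.is_spec.count_range
    isl_lo, isl_hi = config.is_spec.length_range
    ph_lo, ph_hi = config.prophage_spec.count_range
    phl_lo, phl_hi = config.prophage_spec.length_range

    for idx, (acc, sp, spec) in enumerate(zip(accs, species, bcs_specs)):
        chrom = f"{acc}_chr"
        alt = f"{acc}_ctg2"
        zctg = f"{acc}_ctg3"
        g_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(1000, idx))
        )
        contigs[acc] = {chrom: random_sequence(chrom_len, g_rng)}
        contig_lengths[chrom] = chrom_len
        if spec.dispersed:
            contigs[acc][alt] = random_sequence(alt_len, g_rng)
            contig_lengths[alt] = alt_len
        if not spec.qualifies:
            contigs[acc][zctg] = random_sequence(alt_len, g_rng)
            contig_lengths[zctg] = alt_len

        rows, bcs_truth, occupied = _plant_bcs(
            acc, spec, chrom, alt, zctg, chrom_len, alt_len, per_genome_proteins[acc]
        )
        feature_rows.extend(rows)

        n_ph = int(rng_elem.integers(ph_lo, ph_hi + 1))
        ph_lengths = [int(rng_elem.integers(phl_lo, phl_hi + 1)) for _ in range(n_ph)]
        ph_iv = _place_intervals(ph_lengths, chrom_len, occupied, rng_elem)
        occupied = occupied + ph_iv
        n_is = int(rng_elem.integers(is_lo, is_hi + 1))
        is_lengths = [int(rng_elem.integers(isl_lo, isl_hi + 1)) for _ in range(n_is)]
        is_iv = _place_intervals(is_lengths, chrom_len, occupied, rng_elem)

        for k, (s, e) in enumerate(is_iv):
            element_rows.append(
                {"genome": acc, "element_type": "IS", "contig": chrom,
                 "start": s, "end": e, "label": f"IS_fam{1 + k % 5}"}
            )
        for k, (s, e) in enumerate(ph_iv):
            element_rows.append(
                {"genome": acc, "element_type": "prophage_region", "contig": chrom,
                 "start": s, "end": e, "label": f"region_{k + 1}"}
            )
        genome_truth[acc] = {
            "species": sp,
            "anchor": bcs_truth,
            "is": {
                "count": n_is,
                "total_length_bp": int(sum(e - s + 1 for s, e in is_iv)),
            },
            "prophage": {
                "count": n_ph,
                "lengths": sorted(e - s + 1 for s, e in ph_iv),
                "total_length_bp": int(sum(e - s + 1 for s, e in ph_iv)),
            },
        }

    # --- plasmid families
    plasmids: list[SynthPlasmid] = []
    products: dict[str, tuple[str, ...]] = {}
    family_truth: dict[str, dict] = {}
    plasmid_truth: dict[str, dict] = {}
    host_cycle = 0
    for fam in config.plasmid_families:
        hosts = fam.hosts
        if hosts is None:
            hosts = tuple(
                accs[(host_cycle + i) % len(accs)] for i in range(fam.n_members)
            )
            host_cycle += fam.n_members
        if fam.mode == "mosaic":
            module = random_sequence(fam.backbone_length, rng_plasmid)
            seqs = plant_mosaic_family(module, fam.n_members, fam.module_fraction, rng_plasmid)
        else:
            backbone = random_sequence(fam.backbone_length, rng_plasmid)
            seqs = [
                mutate_backbone(backbone, fam.mutation_rate, rng_plasmid)[0]
                for _ in range(fam.n_members)
            ]
        member_ids = [
            f"{host}|p_{fam.name}_{i + 1}" for i, host in enumerate(hosts)
        ]
        for pid, host, seq in zip(member_ids, hosts, seqs):
            plasmids.append(
                SynthPlasmid(
                    plasmid_id=pid, host=host, family=fam.name, sequence=seq,
                    expected_category=fam.expected_category,
                )
            )
            plasmid_truth[pid] = {
                "family": fam.name, "host": host, "length": len(seq),
                "expected_category": fam.expected_category,
            }
        products.update(_family_products(fam, member_ids, rng_plasmid))
        family_truth[fam.name] = {
            "mode": fam.mode,
            "n_members": fam.n_members,
            "expected_category": fam.expected_category,
            "members": member_ids,
            "hosts": list(hosts),
            "mutation_rate": fam.mutation_rate,
            "module_fraction": fam.module_fraction if fam.mode == "mosaic" else None,
        }

    # --- mobility table
    mobility_rows = []
    relaxases = ("MOBQ", "MOBF", "MOBP")
    mob_cats = ("conjugative", "mobilizable", "non-mobilizable", "unknown")
    for p in plasmids:
        cat = mob_cats[int(rng_mob.choice(4, p=(0.2, 0.3, 0.1, 0.4)))]
        relax = (
            relaxases[int(rng_mob.integers(0, 3))]
            if cat in ("conjugative", "mobilizable")
            else "-"
        )
        mobility_rows.append(
            {"plasmid_id": p.plasmid_id, "host_accession": p.host,
             "predicted_mobility": cat, "relaxase_type": relax}
        )
    mobility = pd.DataFrame(
        mobility_rows,
        columns=["plasmid_id", "host_accession", "predicted_mobility", "relaxase_type"],
    )

    # --- pangenome membership
    pan = config.pangenome_spec
    mem_rows = []
    for c in range(pan.n_core):
        mem_rows.append((f"GC_C{c + 1:05d}", list(accs)))
    for a in range(pan.n_accessory):
        size = int(rng_pan.integers(2, max(3, n)))
        members = sorted(rng_pan.choice(n, size=min(size, n - 1), replace=False).tolist())
        mem_rows.append((f"GC_A{a + 1:05d}", [accs[i] for i in members]))
    singleton_counts = {}
    s_lo, s_hi = pan.singleton_range
    for i, acc in enumerate(accs):
        k = int(rng_pan.integers(s_lo, s_hi + 1))
        singleton_counts[acc] = k
        for j in range(k):
            mem_rows.append((f"GC_S{i + 1:02d}_{j + 1:04d}", [acc]))
    membership = pd.DataFrame(
        0, index=pd.Index([r[0] for r in mem_rows], name="cluster_id"),
        columns=pd.Index(accs, name="genome"), dtype=int,
    )
    for cid, members in mem_rows:
        membership.loc[cid, members] = 1
    accessory_counts = {
        acc: int(
            membership.loc[membership.index.str.startswith("GC_A"), acc].sum()
        )
        for acc in accs
    }
    for acc in accs:
        genome_truth[acc]["membership"] = {
            "core": pan.n_core,
            "accessory": accessory_counts[acc],
            "singleton": singleton_counts[acc],
        }

    # --- manifest
    plasmid_bp = {acc: 0 for acc in accs}
    for p in plasmids:
        plasmid_bp[p.host] += len(p.sequence)
    records = tuple(
        GenomeRecord(
            accession=acc,
            species=sp,
            strain=f"syn{idx + 1:02d}",
            size_bp=sum(len(s) for s in contigs[acc].values()) + plasmid_bp[acc],
            source="synthetic",
            excluded_clonal=False,
        )
        for idx, (acc, sp) in enumerate(zip(accs, species))
    )
    manifest = GenomeManifest(records=records, provenance=f"komagen-synth seed={config.seed}")

    features = pd.DataFrame(
        feature_rows,
        columns=["genome", "contig", "start", "end", "strand", "gene", "product",
                 "domains", "protein"],
    )
    elements = pd.DataFrame(
        element_rows,
        columns=["genome", "element_type", "contig", "start", "end", "label"],
    )
    truth = TruthSet(
        seed=config.seed, genomes=genome_truth, families=family_truth,
        plasmids=plasmid_truth,
    )
    return SyntheticGenomeSet(
        config=config, manifest=manifest, contigs=contigs,
        contig_lengths=contig_lengths, plasmids=plasmids, features=features,
        elements=elements, membership=membership, products=products,
        mobility=mobility, truth=truth,
    )


def asdict_shallow(config: SynthConfig) -> dict:
    """Shallow field dict of a config (nested specs kept as objects)."""
    return {f: getattr(config, f) for f in SynthConfig.__dataclass_fields__}


def simulate_linkage_table(
    n_genomes: int,
    n_features: int,
    rng: np.random.Generator,
    planted_rho: float | None = None,
    planted_pair: tuple[int, int] = (0, 1),
) -> pd.DataFrame:
    """Per-genome feature table with independent columns, optionally one
    planted monotone dependency.

    Columns are standard-normal draws; when ``planted_rho`` is given the
    second column of ``planted_pair`` is a Gaussian mixture
    ``rho * x + sqrt(1 - rho^2) * noise`` of the first, a monotone-in-
    expectation dependency of the requested strength.  Used for the type-I
    and power properties of :func:`komagen.pangenome.linkage_analysis`.
    """
    x = rng.standard_normal((n_genomes, n_features))
    if planted_rho is not None:
        i, j = planted_pair
        x[:, j] = planted_rho * x[:, i] + np.sqrt(1 - planted_rho**2) * x[:, j]
    cols = [f"v{k + 1}" for k in range(n_features)]
    idx = pd.Index([_accession(k + 1) for k in range(n_genomes)], name="genome")
    return pd.DataFrame(x, index=idx, columns=cols)
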