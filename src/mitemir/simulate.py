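"""Synthetic genomes with planted MITEs, miRNA loci and cleavage targets.

The generator emulates the data a MITE-derived miRNA screen consumes:

* a genome containing gene models (5'UTR / CDS / intron / CDS / 3'UTR),
  MITE insertions with terminal inverted repeats (TIRs) flanked by a
  duplicated target site (TSD, canonically "TA" for Stowaway-like
  elements), and hairpin-forming miRNA loci — a configurable fraction of
  which sit inside MITE copies, where one TIR arm is long enough to host
  the mature sequence;
* collapsed small-RNA read populations concentrated on the mature and
  star sequences (plus 3' length variants) in the 20-24 nt Dicer size
  classes, with scattered background reads and mixed-strand noise
  islands;
* degradome 5'-end count tables with a sharp spike at each planted
  cleavage site, positioned opposite miRNA position 10;
* a ground-truth manifest sufficient for recovery testing without ever
  reading the generator's internals.

Planted hairpin stems carry exactly one engineered mismatch opposite the
middle of the mature sequence.  Real miRNA/miRNA* duplexes are imperfect,
and a perfect stem would make the two arms exact reverse complements of
each other, letting every mature read also exact-map to the opposite
strand of its own precursor; one duplex mismatch keeps the hairpin valid
(one 1-nt bulge per arm) while making read placement strand-unambiguous.
For the same reason, genomic MITE copies that are not the miRNA
production locus are forced to diverge inside the mature/star footprints.

All randomness flows from ``SimConfig.seed``; a fixed seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import revcomp
from .fileio import (
    GffFeature,
    transcript_models_from_gff,
    write_collapsed_fasta,
    write_degradome_tsv,
    write_fasta,
    write_gff3,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    genome_length: int = 150_000
    n_chromosomes: int = 2
    n_genes: int = 10
    n_mite_families: int = 6
    mite_length_range: tuple[int, int] = (100, 600)
    hosting_mite_length_range: tuple[int, int] = (120, 185)
    tir_length: int = 12
    hosting_tir_length: int = 26
    tsd: str = "TA"
    n_mite_copies: int = 14
    copy_divergence: float = 0.02
    n_mirna_loci: int = 10
    frac_mite_derived: float = 0.4
    mature_length_weights: dict[int, float] = field(
        default_factory=lambda: {20: 0.07, 21: 0.65, 22: 0.13, 23: 0.03, 24: 0.13}
    )
    reads_per_locus: int = 100
    noise_reads: int = 60
    n_noise_islands: int = 2
    n_srna_libraries: int = 3
    n_target_sites: int = 6
    degradome_depth: float = 40.0
    slice_spike: float = 20.0

    def validate(self) -> None:
        if not 0.0 <= self.copy_divergence <= 0.2:
            raise ValueError("copy_divergence must be in [0, 0.2]")
        if not 0.0 <= self.frac_mite_derived <= 1.0:
            raise ValueError("frac_mite_derived must be in [0, 1]")
        total_w = sum(self.mature_length_weights.values())
        # observed size-class shares are rounded percentages; allow slight
        # departure from 1 and renormalise when sampling
        if not 0.95 <= total_w <= 1.05 or min(self.mature_length_weights.values()) < 0:
            raise ValueError("mature_length_weights must be non-negative and sum to ~1")
        if not all(20 <= k <= 24 for k in self.mature_length_weights):
            raise ValueError("mature lengths must lie in 20..24")
        if self.n_target_sites > self.n_genes:
            raise ValueError("n_target_sites cannot exceed n_genes")
        if self.n_target_sites > self.n_mirna_loci:
            raise ValueError("n_target_sites cannot exceed n_mirna_loci")
        if len(self.tsd) < 1:
            raise ValueError("tsd must be non-empty")


@dataclass
class PlantedMite:
    family: str
    chrom: str
    start: int  # 1-based inclusive, MITE body (TSD excluded)
    end: int
    strand: str
    context: str


@dataclass
class PlantedMirna:
    mirna_id: str
    chrom: str
    start: int  # locus span: mature 5' end .. star 3' end
    end: int
    strand: str
    mature: str
    mature_start: int
    star: str
    star_start: int
    is_mite_derived: bool
    family: str | None
    context: str


@dataclass
class PlantedTarget:
    mirna_id: str
    transcript_id: str
    site_start: int  # 1-based transcript coordinate of the target site
    cleavage_position: int  # transcript base paired to miRNA position 10
    has_mite_in_target: bool


@dataclass
class SyntheticTruth:
    planted_mites: list[PlantedMite] = field(default_factory=list)
    planted_mirnas: list[PlantedMirna] = field(default_factory=list)
    planted_targets: list[PlantedTarget] = field(default_factory=list)
    families: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "planted_mites": [asdict(m) for m in self.planted_mites],
            "planted_mirnas": [asdict(m) for m in self.planted_mirnas],
            "planted_targets": [asdict(t) for t in self.planted_targets],
            "families": self.families,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        doc = json.loads(Path(path).read_text())
        return cls(
            [PlantedMite(**m) for m in doc["planted_mites"]],
            [PlantedMirna(**m) for m in doc["planted_mirnas"]],
            [PlantedTarget(**t) for t in doc["planted_targets"]],
            doc["families"],
        )


# ------------------------------------------------------------------ helpers

def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    if n <= 0:
        return ""
    letters = np.frombuffer(alphabet.encode(), dtype="S1")
    return rng.choice(letters, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mask = rng.random(len(arr)) < rate
    for i in np.nonzero(mask)[0]:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[rng.integers(0, 3)]])
    return arr.tobytes().decode()


def _force_mutate(rng: np.random.Generator, seq: str, lo: int, hi: int, n: int = 2) -> str:
    """Guarantee >= n substitutions inside seq[lo:hi] (0-based half-open)."""
    arr = list(seq)
    positions = rng.choice(np.arange(lo, hi), size=min(n, hi - lo), replace=False)
    for p in positions:
        alts = [b for b in "ACGT" if b != arr[p]]
        arr[p] = alts[rng.integers(0, 3)]
    return "".join(arr)


_NONPAIRING_SUB = {"A": "C", "U": "C", "T": "C", "G": "A", "C": "A"}


def sample_mature_lengths(rng: np.random.Generator, n: int, weights: dict[int, float]) -> list[int]:
    lengths = sorted(weights)
    probs = np.array([weights[k] for k in lengths], dtype=float)
    probs = probs / probs.sum()
    return [int(x) for x in rng.choice(lengths, size=n, p=probs)]


def _make_family(rng: np.random.Generator, length: int, tir_len: int) -> str:
    """A MITE consensus: TIR + core + reverse-complemented TIR."""
    tir = _rand_seq(rng, tir_len)
    core = _rand_seq(rng, length - 2 * tir_len)
    return tir + core + revcomp(tir)


def _hosting_family(rng: np.random.Generator, length: int, tir_len: int, mature_len: int) -> tuple[str, str]:
    """A MITE consensus whose 5' TIR hosts a mature miRNA at offset 2, with
    one engineered duplex mismatch opposite the middle of the mature."""
    cons = _make_family(rng, length, tir_len)
    q = 2 + mature_len // 2  # middle of the mature footprint
    partner = length - 1 - q
    cons = cons[:partner] + _NONPAIRING_SUB[cons[q]] + cons[partner + 1 :]
    mature = cons[2 : 2 + mature_len]
    return cons, mature


# ------------------------------------------------------------ genome blocks

@dataclass
class _Block:
    """A contiguous stretch of assembled sequence plus relative records."""

    seq: str
    # (kind, payload) records carrying 0-based offsets relative to the block
    records: list[tuple[str, dict]] = field(default_factory=list)


def _hairpin_block(rng: np.random.Generator, mature_len: int, mirna_id: str, context: str) -> _Block:
    """A standalone hairpin miRNA locus: flank + mature arm + loop + star arm
    + flank, with one duplex mismatch opposite the mature's middle."""
    f5 = _rand_seq(rng, 10, "AC")
    f3 = _rand_seq(rng, 10, "AC")
    loop = _rand_seq(rng, 7, "AC")
    mature = _rand_seq(rng, mature_len)
    arm2 = list(revcomp(mature))
    # partner of mature index q sits at arm2 index mature_len - 1 - q
    q = mature_len // 2
    arm2[mature_len - 1 - q] = _NONPAIRING_SUB[mature[q]]
    arm2 = "".join(arm2)
    seq = f5 + mature + loop + arm2 + f3
    mature_off = len(f5)
    star_off = len(f5) + mature_len + len(loop) + 2
    star_len = mature_len  # arm2 tail (L-2) plus 2-nt 3' overhang into f3
    rec = {
        "mirna_id": mirna_id,
        "mature_off": mature_off,
        "mature_len": mature_len,
        "star_off": star_off,
        "star_len": star_len,
        "is_mite_derived": False,
        "family": None,
        "context": context,
    }
    return _Block(seq, [("mirna", rec)])


def _mite_copy_block(
    rng: np.random.Generator,
    config: SimConfig,
    family: str,
    consensus: str,
    context: str,
    kind: str,
    mature_len: int = 0,
    mirna_id: str = "",
) -> _Block:
    """One genomic MITE insertion: TSD + copy + TSD.

    kind "hosting": the miRNA production copy — TIR footprints kept exact.
    kind "target":  carries the exact complementary site at the 3' TIR; the
                    mature footprint at the 5' TIR is forced to diverge.
    kind "generic": ordinary copy; if the family hosts a miRNA, both the
                    mature and star footprints are forced to diverge.
    """
    tsd = config.tsd
    n = len(consensus)
    if kind == "hosting":
        core_lo, core_hi = 2 + mature_len, n - mature_len - 2
        copy = consensus[:core_lo] + _mutate(rng, consensus[core_lo:core_hi], config.copy_divergence) + consensus[core_hi:]
    elif kind == "target":
        copy = consensus[: n // 2] + _mutate(rng, consensus[n // 2 : n - mature_len - 2], config.copy_divergence) + consensus[n - mature_len - 2 :]
        copy = _force_mutate(rng, copy, 2, 2 + mature_len)
    else:
        copy = _mutate(rng, consensus, config.copy_divergence)
        if mature_len:
            copy = _force_mutate(rng, copy, 2, 2 + mature_len)
            copy = _force_mutate(rng, copy, n - mature_len, n)
    seq = tsd + copy + tsd
    records: list[tuple[str, dict]] = [
        ("mite", {"family": family, "off": len(tsd), "length": n, "context": context})
    ]
    if kind == "hosting":
        records.append(
            (
                "mirna",
                {
                    "mirna_id": mirna_id,
                    "mature_off": len(tsd) + 2,
                    "mature_len": mature_len,
                    "star_off": len(tsd) + n - mature_len,
                    "star_len": mature_len,
                    "is_mite_derived": True,
                    "family": family,
                    "context": context,
                },
            )
        )
    if kind == "target":
        records.append(
            ("site", {"off": len(tsd) + n - 2 - mature_len, "length": mature_len})
        )
    return _Block(seq, records)


def _splice_blocks(
    rng: np.random.Generator, region: str, blocks: list[_Block]
) -> tuple[str, list[tuple[int, _Block]]]:
    """Insert blocks into a region at random positions; returns the new
    region and each block's final 0-based offset."""
    if not blocks:
        return region, []
    offs = sorted(int(rng.integers(5, max(6, len(region) - 5))) for _ in blocks)
    out = []
    shift = 0
    pieces = []
    prev = 0
    for off, block in zip(offs, blocks):
        pieces.append(region[prev:off])
        out.append((off + shift, block))
        pieces.append(block.seq)
        shift += len(block.seq)
        prev = off
    pieces.append(region[prev:])
    return "".join(pieces), out


def _gene_block(
    rng: np.random.Generator,
    gene_id: str,
    intron_blocks: list[_Block],
    utr3_blocks: list[_Block],
    cds_blocks: list[_Block],
    utr5_blocks: list[_Block],
) -> _Block:
    """A plus-strand two-exon gene with optional insertions per region."""
    u5 = _rand_seq(rng, int(rng.integers(100, 200)))
    cds1 = _rand_seq(rng, int(rng.integers(150, 300)))
    intron = _rand_seq(rng, int(rng.integers(150, 400)))
    cds2 = _rand_seq(rng, int(rng.integers(150, 300)))
    u3 = _rand_seq(rng, int(rng.integers(250, 450)))

    u5, u5_placed = _splice_blocks(rng, u5, utr5_blocks)
    cds2, cds_placed = _splice_blocks(rng, cds2, cds_blocks)
    intron, intron_placed = _splice_blocks(rng, intron, intron_blocks)
    u3, u3_placed = _splice_blocks(rng, u3, utr3_blocks)

    seq = u5 + cds1 + intron + cds2 + u3
    records: list[tuple[str, dict]] = [
        (
            "gene",
            {
                "gene_id": gene_id,
                "u5": len(u5),
                "cds1": len(cds1),
                "intron": len(intron),
                "cds2": len(cds2),
                "u3": len(u3),
            },
        )
    ]

    region_offsets = {
        "five_prime_UTR": 0,
        "CDS": len(u5) + len(cds1) + len(intron),
        "intron": len(u5) + len(cds1),
        "three_prime_UTR": len(u5) + len(cds1) + len(intron) + len(cds2),
    }
    # transcript-coordinate prefix of each spliced region
    tx_prefix = {
        "five_prime_UTR": 0,
        "CDS": len(u5) + len(cds1),
        "three_prime_UTR": len(u5) + len(cds1) + len(cds2),
    }
    for region, placed in (
        ("five_prime_UTR", u5_placed),
        ("CDS", cds_placed),
        ("intron", intron_placed),
        ("three_prime_UTR", u3_placed),
    ):
        for off, block in placed:
            for kind, payload in block.records:
                payload = dict(payload)
                if kind in ("mite", "mirna"):
                    if kind == "mite":
                        payload["off"] = region_offsets[region] + off + payload["off"]
                        payload["context"] = region if region != "CDS" else "exon"
                    else:
                        payload["mature_off"] = region_offsets[region] + off + payload["mature_off"]
                        payload["star_off"] = region_offsets[region] + off + payload["star_off"]
                        payload["context"] = region
                        payload["gene_id"] = gene_id
                    records.append((kind, payload))
                elif kind == "site":
                    if region == "intron":
                        raise ValueError("target sites cannot be planted in introns")
                    payload["tx_pos"] = tx_prefix[region] + off + payload["off"]  # 0-based
                    payload["region"] = region
                    payload["gene_id"] = gene_id
                    records.append((kind, payload))
    return _Block(seq, records)


# ------------------------------------------------------------ main generator

def generate_genome(config: SimConfig) -> tuple[dict[str, str], list[GffFeature], SyntheticTruth]:
    """Assemble the genome, gene annotation and ground-truth manifest."""
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    truth = SyntheticTruth()

    n_mite_derived = round(config.frac_mite_derived * config.n_mirna_loci)
    mature_lengths = sample_mature_lengths(rng, config.n_mirna_loci, config.mature_length_weights)

    # --- families (first n_mite_derived host a miRNA in their 5' TIR)
    n_fam = max(config.n_mite_families, n_mite_derived)
    families: dict[str, str] = {}
    hosting_mature: dict[str, str] = {}
    fam_ids = [f"MITE_{i:03d}" for i in range(n_fam)]
    for i, fam in enumerate(fam_ids):
        if i < n_mite_derived:
            lo, hi = config.hosting_mite_length_range
            tir = max(config.hosting_tir_length, mature_lengths[i] + 4)
            length = int(rng.integers(max(lo, 2 * tir + 10), hi + 1))
            cons, mature = _hosting_family(rng, length, tir, mature_lengths[i])
            families[fam] = cons
            hosting_mature[fam] = mature
        else:
            lo, hi = config.mite_length_range
            length = int(rng.integers(max(lo, 2 * config.tir_length + 10), hi + 1))
            families[fam] = _make_family(rng, length, config.tir_length)
    truth.families = dict(families)

    # --- miRNA loci: contexts and block construction
    mirna_ids = [f"mir_{i:02d}" for i in range(config.n_mirna_loci)]
    contexts = rng.choice(
        ["intergenic", "intron", "promoter"], size=config.n_mirna_loci, p=[0.70, 0.25, 0.05]
    )
    mirna_blocks: list[tuple[str, _Block]] = []  # (context, block)
    for i in range(config.n_mirna_loci):
        ctx = str(contexts[i])
        if i < n_mite_derived:
            fam = fam_ids[i]
            block = _mite_copy_block(
                rng, config, fam, families[fam], ctx, "hosting",
                mature_len=mature_lengths[i], mirna_id=mirna_ids[i],
            )
        else:
            block = _hairpin_block(rng, mature_lengths[i], mirna_ids[i], ctx)
        mirna_blocks.append((ctx, block))

    # --- target sites: MITE-derived miRNAs target MITE copies in 3' UTRs,
    # the rest get an exact complementary site in a sampled transcript region
    target_mirnas = list(range(min(config.n_target_sites, config.n_mirna_loci)))
    target_blocks: list[tuple[int, str, _Block]] = []  # (gene index, region, block)
    target_genes = list(rng.permutation(config.n_genes))[: len(target_mirnas)]
    target_meta: dict[str, dict] = {}
    for gi, mi in zip(target_genes, target_mirnas):
        mid = mirna_ids[mi]
        if mi < n_mite_derived:
            fam = fam_ids[mi]
            block = _mite_copy_block(
                rng, config, fam, families[fam], "three_prime_UTR", "target",
                mature_len=mature_lengths[mi],
            )
            region = "three_prime_UTR"
            has_mite = True
        else:
            region = str(rng.choice(["five_prime_UTR", "CDS", "three_prime_UTR"], p=[0.2, 0.2, 0.6]))
            # placeholder; replaced below with the exact reverse complement
            # of the mature once the hairpin block is known
            block = _Block("", [("site", {"off": 0, "length": mature_lengths[mi]})])
            has_mite = False
        target_blocks.append((int(gi), region, block))
        target_meta[mid] = {"has_mite": has_mite, "mirna_index": mi}

    # non-MITE target blocks need the mature sequence; hairpin blocks know it
    for idx, (gi, region, block) in enumerate(target_blocks):
        mi = target_mirnas[idx]
        if mi >= n_mite_derived:
            _, hp_block = mirna_blocks[mi]
            rec = dict(hp_block.records[0][1])
            mature = hp_block.seq[rec["mature_off"] : rec["mature_off"] + rec["mature_len"]]
            target_blocks[idx] = (gi, region, _Block(revcomp(mature), [("site", {"off": 0, "length": len(mature)})]))
        # tag the site with its miRNA for the manifest
        for kind, payload in target_blocks[idx][2].records:
            if kind == "site":
                payload["mirna_id"] = mirna_ids[mi]

    # --- generic MITE copies
    copy_contexts = rng.choice(
        ["intergenic", "intron", "promoter", "three_prime_UTR"],
        size=config.n_mite_copies, p=[0.50, 0.25, 0.15, 0.10],
    )
    copy_blocks: list[tuple[str, _Block]] = []
    for ctx in copy_contexts:
        fam = fam_ids[int(rng.integers(0, n_fam))]
        mlen = len(hosting_mature[fam]) if fam in hosting_mature else 0
        block = _mite_copy_block(rng, config, fam, families[fam], str(ctx), "generic", mature_len=mlen)
        copy_blocks.append((str(ctx), block))

    # --- distribute insertions over genes
    per_gene_regions: list[dict[str, list[_Block]]] = [
        {"intron": [], "three_prime_UTR": [], "CDS": [], "five_prime_UTR": []}
        for _ in range(config.n_genes)
    ]
    promoter_blocks_per_gene: list[list[_Block]] = [[] for _ in range(config.n_genes)]
    intergenic_blocks: list[_Block] = []

    for gi, region, block in target_blocks:
        per_gene_regions[gi][region].append(block)

    mirna_intron_genes: set[int] = set()
    mirna_promoter_genes: set[int] = set()

    def place(ctx: str, block: _Block, is_mirna: bool = False) -> None:
        if config.n_genes == 0 and ctx != "intergenic":
            ctx = "intergenic"
        if ctx == "intergenic":
            intergenic_blocks.append(block)
        elif ctx == "promoter":
            # keep promoters hosting a miRNA block free of other inserts,
            # so multi-mapping background reads cannot stretch its cluster
            if is_mirna:
                free = [g for g in range(config.n_genes) if g not in mirna_promoter_genes and not promoter_blocks_per_gene[g]]
                if not free:
                    for _, payload in block.records:
                        if "context" in payload:
                            payload["context"] = "intergenic"
                    intergenic_blocks.append(block)
                    return
                gi = int(free[rng.integers(0, len(free))])
                mirna_promoter_genes.add(gi)
            else:
                free = [g for g in range(config.n_genes) if g not in mirna_promoter_genes]
                gi = int(free[rng.integers(0, len(free))]) if free else int(rng.integers(0, config.n_genes))
            promoter_blocks_per_gene[gi].append(block)
        else:
            region = "intron" if ctx == "intron" else "three_prime_UTR"
            if is_mirna and region == "intron":
                # one read-producing locus per intron, so neighbouring
                # planted loci can never merge into a single sRNA cluster
                free = [g for g in range(config.n_genes) if g not in mirna_intron_genes]
                if not free:
                    for _, payload in block.records:
                        if "context" in payload:
                            payload["context"] = "intergenic"
                    intergenic_blocks.append(block)
                    return
                gi = int(free[rng.integers(0, len(free))])
                mirna_intron_genes.add(gi)
            else:
                if region == "intron":
                    free = [g for g in range(config.n_genes) if g not in mirna_intron_genes]
                    gi = int(free[rng.integers(0, len(free))]) if free else int(rng.integers(0, config.n_genes))
                else:
                    gi = int(rng.integers(0, config.n_genes))
            per_gene_regions[gi][region].append(block)

    for ctx, block in mirna_blocks:
        place(ctx, block, is_mirna=True)
    for ctx, block in copy_blocks:
        place(ctx, block)

    # --- assemble gene blocks, then pack everything with intergenic spacers
    blocks: list[_Block] = []
    for gi in range(config.n_genes):
        gene = _gene_block(
            rng, f"GENE_{gi:03d}",
            per_gene_regions[gi]["intron"], per_gene_regions[gi]["three_prime_UTR"],
            per_gene_regions[gi]["CDS"], per_gene_regions[gi]["five_prime_UTR"],
        )
        upstream = promoter_blocks_per_gene[gi]
        if upstream:
            parts: list[_Block] = []
            combined_seq = ""
            combined_records: list[tuple[str, dict]] = []
            for ub in upstream:
                gap = int(rng.integers(150, max(200, 1900 - len(ub.seq))))
                for kind, payload in ub.records:
                    payload = dict(payload)
                    shift = len(combined_seq)
                    if kind == "mite":
                        payload["off"] += shift
                        payload["context"] = "promoter"
                    elif kind == "mirna":
                        payload["mature_off"] += shift
                        payload["star_off"] += shift
                        payload["context"] = "promoter"
                        payload["gene_id"] = f"GENE_{gi:03d}"
                    combined_records.append((kind, payload))
                combined_seq += ub.seq + _rand_seq(rng, gap)
            shift = len(combined_seq)
            for kind, payload in gene.records:
                payload = dict(payload)
                if kind == "gene":
                    payload["gene_off"] = shift
                elif kind == "mite":
                    payload["off"] += shift
                elif kind == "mirna":
                    payload["mature_off"] += shift
                    payload["star_off"] += shift
                elif kind == "site":
                    pass  # transcript coordinates are gene-internal
                combined_records.append((kind, payload))
            blocks.append(_Block(combined_seq + gene.seq, combined_records))
        else:
            recs = []
            for kind, payload in gene.records:
                payload = dict(payload)
                if kind == "gene":
                    payload["gene_off"] = 0
                recs.append((kind, payload))
            blocks.append(_Block(gene.seq, recs))
    blocks.extend(intergenic_blocks)

    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    assignment = [i % config.n_chromosomes for i in range(len(blocks))]

    total_block_len = sum(len(b.seq) for b in blocks)
    n_spacers = len(blocks) + config.n_chromosomes
    min_spacer = 150
    budget = config.genome_length - total_block_len
    if budget < min_spacer * n_spacers:
        raise ValueError(
            f"infeasible packing: features need {total_block_len + min_spacer * n_spacers} nt "
            f"but genome_length is {config.genome_length}"
        )
    extra = rng.multinomial(budget - min_spacer * n_spacers, [1.0 / n_spacers] * n_spacers)
    spacer_lengths = [min_spacer + int(x) for x in extra]

    genome: dict[str, str] = {}
    features: list[GffFeature] = []
    gene_tx_records: dict[str, dict] = {}
    spacer_i = 0
    per_chrom_blocks: dict[str, list[_Block]] = {c: [] for c in chrom_names}
    for b, ci in zip(blocks, assignment):
        per_chrom_blocks[chrom_names[ci]].append(b)

    for chrom in chrom_names:
        parts = []
        pos = 0  # 0-based running offset
        sp = _rand_seq(rng, spacer_lengths[spacer_i]); spacer_i += 1
        parts.append(sp); pos += len(sp)
        for block in per_chrom_blocks[chrom]:
            base = pos  # block start, 0-based
            for kind, payload in block.records:
                if kind == "gene":
                    g0 = base + payload["gene_off"]  # 0-based gene start
                    gene_tx_records[payload["gene_id"]] = dict(payload, chrom=chrom, g0=g0)
                elif kind == "mite":
                    s = base + payload["off"]
                    truth.planted_mites.append(
                        PlantedMite(payload["family"], chrom, s + 1, s + payload["length"], "+", payload["context"])
                    )
                elif kind == "mirna":
                    ms = base + payload["mature_off"]
                    ss = base + payload["star_off"]
                    truth.planted_mirnas.append(
                        PlantedMirna(
                            payload["mirna_id"], chrom,
                            ms + 1, ss + payload["star_len"], "+",
                            "", ms + 1, "", ss + 1,
                            payload["is_mite_derived"], payload["family"], payload["context"],
                        )
                    )
                elif kind == "site":
                    gid = payload.get("gene_id")
                    truth.planted_targets.append(
                        PlantedTarget(
                            payload["mirna_id"], f"{gid}.1",
                            payload["tx_pos"] + 1,
                            payload["tx_pos"] + payload["length"] - 9,
                            False,  # resolved from target_meta below
                        )
                    )
            parts.append(block.seq); pos += len(block.seq)
            sp = _rand_seq(rng, spacer_lengths[spacer_i]); spacer_i += 1
            parts.append(sp); pos += len(sp)
        genome[chrom] = "".join(parts)

    # fix up target has_mite flags (site blocks from MITE copies carry "length"
    # of the site; flag known from target_meta)
    for t in truth.planted_targets:
        t.has_mite_in_target = target_meta.get(t.mirna_id, {}).get("has_mite", False)

    # --- GFF features for genes
    for gid in sorted(gene_tx_records):
        r = gene_tx_records[gid]
        chrom, g0 = r["chrom"], r["g0"]
        u5, cds1, intron, cds2, u3 = r["u5"], r["cds1"], r["intron"], r["cds2"], r["u3"]
        start = g0 + 1
        end = g0 + u5 + cds1 + intron + cds2 + u3
        tid = f"{gid}.1"
        exon1 = (start, g0 + u5 + cds1)
        exon2 = (g0 + u5 + cds1 + intron + 1, end)
        features.append(GffFeature(chrom, "mitemir_sim", "gene", start, end, ".", "+", ".", {"ID": gid}))
        features.append(GffFeature(chrom, "mitemir_sim", "mRNA", start, end, ".", "+", ".", {"ID": tid, "Parent": gid}))
        features.append(GffFeature(chrom, "mitemir_sim", "exon", exon1[0], exon1[1], ".", "+", ".", {"ID": f"{tid}.exon1", "Parent": tid}))
        features.append(GffFeature(chrom, "mitemir_sim", "exon", exon2[0], exon2[1], ".", "+", ".", {"ID": f"{tid}.exon2", "Parent": tid}))
        features.append(GffFeature(chrom, "mitemir_sim", "five_prime_UTR", start, g0 + u5, ".", "+", ".", {"ID": f"{tid}.utr5", "Parent": tid}))
        features.append(GffFeature(chrom, "mitemir_sim", "CDS", g0 + u5 + 1, g0 + u5 + cds1, ".", "+", "0", {"ID": f"{tid}.cds1", "Parent": tid}))
        features.append(GffFeature(chrom, "mitemir_sim", "CDS", exon2[0], exon2[0] + cds2 - 1, ".", "+", "0", {"ID": f"{tid}.cds2", "Parent": tid}))
        features.append(GffFeature(chrom, "mitemir_sim", "three_prime_UTR", exon2[0] + cds2, end, ".", "+", ".", {"ID": f"{tid}.utr3", "Parent": tid}))
    features.sort(key=lambda f: (f.chrom, f.start, f.type != "gene"))

    # --- resolve mature/star sequences from the assembled genome
    # (both planting geometries use star_len == mature_len)
    for m in truth.planted_mirnas:
        seq = genome[m.chrom]
        L = m.end - m.star_start + 1
        m.mature = seq[m.mature_start - 1 : m.mature_start - 1 + L]
        m.star = seq[m.star_start - 1 : m.end]
    return genome, features, truth


# ------------------------------------------------------------------- reads

def _variant_read(genome: dict[str, str], chrom: str, start: int, length: int, d3: int) -> str:
    """A 3' length variant of a plus-strand read (d3 in -2..+2)."""
    return genome[chrom][start - 1 : start - 1 + length + d3]


def generate_srna_reads(
    truth: SyntheticTruth,
    genome: dict[str, str],
    config: SimConfig,
    library_index: int = 0,
) -> list[tuple[str, int]]:
    """One collapsed sRNA library: mature/star/3'-variant reads for every
    planted miRNA locus plus background noise and mixed-strand islands."""
    if not truth.planted_mirnas and config.noise_reads == 0 and config.n_noise_islands == 0:
        return []
    rng = np.random.default_rng([config.seed, 23, library_index])
    reads: dict[str, int] = {}

    def add(seq: str, count: int) -> None:
        if count > 0 and seq:
            reads[seq] = reads.get(seq, 0) + count

    for m in truth.planted_mirnas:
        expr = float(rng.uniform(0.4, 1.4))  # per-locus, per-library expression
        rpl = config.reads_per_locus * expr
        L = len(m.mature)
        star_n = max(1, int(rng.poisson(0.18 * rpl)))
        mature_n = max(star_n + 1, int(rng.poisson(0.55 * rpl)))
        add(m.mature, mature_n)
        add(m.star, star_n)
        add(_variant_read(genome, m.chrom, m.mature_start, L, +1), int(rng.poisson(0.08 * rpl)))
        add(_variant_read(genome, m.chrom, m.mature_start, L, -1), int(rng.poisson(0.06 * rpl)))
        add(_variant_read(genome, m.chrom, m.star_start, len(m.star), +1), int(rng.poisson(0.04 * rpl)))

    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    # background reads keep clear of planted loci so that cluster bounds
    # (and hence folding windows) of planted miRNAs are noise-free
    exclusion = 400

    def clear_of_loci(chrom: str, pos: int) -> bool:
        return all(
            m.chrom != chrom or not (m.start - exclusion <= pos <= m.end + exclusion)
            for m in truth.planted_mirnas
        )

    def noise_position(min_margin: int) -> tuple[str, int]:
        for _ in range(200):
            chrom = chroms[int(rng.choice(len(chroms), p=probs))]
            pos = int(rng.integers(min_margin, len(genome[chrom]) - min_margin))
            if clear_of_loci(chrom, pos):
                return chrom, pos
        raise ValueError("could not place background reads away from planted loci")

    for _ in range(config.noise_reads):
        L = int(rng.integers(15, 31))
        chrom, start = noise_position(40)
        seq = genome[chrom][start : start + L]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        add(seq, 1)

    for _ in range(config.n_noise_islands):
        chrom, anchor = noise_position(100)
        for j in range(14):
            L = int(rng.integers(20, 25))
            start = anchor + int(rng.integers(0, 30))
            seq = genome[chrom][start : start + L]
            if j % 2:  # alternate strands so the island is unstranded
                seq = revcomp(seq)
            add(seq, int(rng.integers(1, 3)))
    return sorted(reads.items())


def generate_srna_libraries(
    truth: SyntheticTruth, genome: dict[str, str], config: SimConfig
) -> dict[str, list[tuple[str, int]]]:
    return {
        f"lib{i + 1}": generate_srna_reads(truth, genome, config, library_index=i)
        for i in range(config.n_srna_libraries)
    }


# ---------------------------------------------------------------- degradome

def generate_degradome(
    truth: SyntheticTruth,
    transcripts: dict[str, str],
    config: SimConfig,
    library_index: int = 0,
) -> pd.DataFrame:
    """Per-transcript 5'-end counts: low-rate uniform background plus a
    ``slice_spike``-fold spike at every planted cleavage position."""
    rng = np.random.default_rng([config.seed, 37, library_index])
    rows = []
    by_tx: dict[str, list[PlantedTarget]] = {}
    for t in truth.planted_targets:
        if t.transcript_id not in transcripts:
            raise ValueError(f"planted target references unknown transcript {t.transcript_id}")
        if not 1 <= t.cleavage_position <= len(transcripts[t.transcript_id]):
            raise ValueError(f"cleavage position outside transcript {t.transcript_id}")
        by_tx.setdefault(t.transcript_id, []).append(t)
    for tid in sorted(transcripts):
        n = len(transcripts[tid])
        counts = np.zeros(n, dtype=int)
        n_bg = rng.poisson(config.degradome_depth)
        if n_bg > 0:
            positions = rng.integers(0, n, size=n_bg)
            np.add.at(counts, positions, 1)
        positive = counts[counts > 0]
        background_mean = float(positive.mean()) if positive.size else 1.0
        for t in by_tx.get(tid, []):
            counts[t.cleavage_position - 1] += max(2, round(config.slice_spike * background_mean))
        for pos in np.nonzero(counts)[0]:
            rows.append((tid, int(pos) + 1, int(counts[pos])))
    return pd.DataFrame(rows, columns=["transcript_id", "position", "count"])


# ------------------------------------------------------------------- bundle

@dataclass
class SimOutput:
    config: SimConfig
    genome: dict[str, str]
    features: list[GffFeature]
    truth: SyntheticTruth
    libraries: dict[str, list[tuple[str, int]]]
    transcripts: dict[str, str]
    degradome: pd.DataFrame
    mite_candidates: dict[str, str]


def mite_candidate_fasta(truth: SyntheticTruth, config: SimConfig) -> dict[str, str]:
    """The MITE candidate set fed to library clustering: every family
    consensus plus, for alternating families, a slightly diverged twin named
    like a curated-database entry."""
    rng = np.random.default_rng([config.seed, 53])
    out: dict[str, str] = {}
    for i, (fam, cons) in enumerate(sorted(truth.families.items())):
        out[fam] = cons
        if i % 2 == 0:
            out[f"DTT_Syn_{fam}-1"] = _mutate(rng, cons, 0.02)
    return out


def simulate(config: SimConfig) -> SimOutput:
    """Run the full generator: genome, annotation, reads, degradome, truth."""
    genome, features, truth = generate_genome(config)
    models = transcript_models_from_gff(features)
    transcripts = {tid: m.spliced_sequence(genome) for tid, m in models.items()}
    libraries = generate_srna_libraries(truth, genome, config)
    degradome = generate_degradome(truth, transcripts, config)
    return SimOutput(
        config, genome, features, truth, libraries, transcripts, degradome,
        mite_candidate_fasta(truth, config),
    )


def write_simulation(out: SimOutput, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(out.genome, outdir / "genome.fa")
    write_gff3(out.features, outdir / "genes.gff3")
    write_fasta(out.transcripts, outdir / "transcripts.fa")
    write_fasta(out.mite_candidates, outdir / "mite_candidates.fa")
    for lib, reads in out.libraries.items():
        write_collapsed_fasta(reads, outdir / f"srna_{lib}.fa")
    write_degradome_tsv(out.degradome, outdir / "degradome.tsv")
    out.truth.to_json(outdir / "truth.json")
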