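"""Synthetic tri-genome fixtures with planted editing sites.

Generates a self-contained study system: a chloroplast genome carrying
CDS and tRNA features on both strands, a nuclear genome containing exact
plastid-derived insertions (the decoys that motivate chloroplast-first
filtering), a mitochondrial genome free of chloroplast 18-mers, and a
small-RNA read library with per-read Bernoulli editing at planted sites,
i.i.d. substitution sequencing errors, and a machine-readable truth
table.

Everything is a pure function of :class:`SimConfig` (including the seed):
identical configs give byte-identical outputs.

Truth semantics
---------------
* per site: how many emitted reads overlap the site and how many carry
  the edited base (the Bernoulli outcome, recorded before sequencing
  errors are applied);
* per read: its origin (cp_feature / cp_intergenic / nuclear / mito /
  unmappable), coordinates, edited transcript positions, error count and
  — when ``error_rate == 0`` — the partition class the mapping hierarchy
  must assign it.  Expected classes are verified at generation time by an
  independent seed-and-verify scan inside this module (background reads
  that collide with a reference by chance are resampled), so origin
  counts are exact by construction, not by luck.

Generator simplifications (see the methods note): transcript reads are
sense-strand only (antisense contamination is a knob, default 0);
genome-origin reads come from the forward strand of strictly intergenic
windows; nuclear background avoids the insertion intervals.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import refio
from .refio import (
    ConfigError,
    Feature,
    ReadRecord,
    ReferenceSequence,
    ReferenceSet,
    extract_feature_sequence,
    revcomp,
)

__all__ = [
    "EditSiteSpec",
    "SimConfig",
    "SimulatedReferences",
    "SimulatedReads",
    "simulate_references",
    "simulate_reads",
    "write_simulation",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_ALL_CODONS = [
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS
]
_EDIT_BASE = {"C2U": ("C", "T"), "A2I": ("A", "G")}


@dataclass(frozen=True)
class EditSiteSpec:
    """A planted editing site: gene, transcript position, per-read rate.

    ``cds_pos=None`` lets the generator pick a suitable position
    (a C for C2U in a CDS, an A for A2I in a tRNA) deterministically from
    the seeded stream.
    """

    gene: str
    cds_pos: Optional[int]
    rate: float
    etype: str = "C2U"

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ConfigError(f"{self.gene}: rate {self.rate} outside [0,1]")
        if self.etype not in _EDIT_BASE:
            raise ConfigError(f"{self.gene}: unknown edit type {self.etype!r}")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of a simulated study.

    Read-class proportions default to the distribution observed for a
    whole-plant Arabidopsis sRNA library (≈45% nuclear, ≈0.1%
    mitochondrial, ≈23% chloroplast, remainder unmappable); read lengths
    default to uniform on 18–24 nt.
    """

    seed: int = 0
    cp_length: int = 20_000
    nuc_length: int = 50_000
    mt_length: int = 10_000
    n_genes: int = 8
    n_trnas: int = 3
    gene_length: int = 450  # nt incl. start/stop, divisible by 3
    trna_length: int = 74
    insertion_count: int = 2
    insertion_length: int = 120
    edit_sites: tuple[EditSiteSpec, ...] = ()
    read_count: int = 50_000
    length_dist: Optional[dict[int, float]] = None
    error_rate: float = 0.0
    mrna_mode: bool = False
    p_nuclear: float = 0.45
    p_mito: float = 0.001
    p_cp: float = 0.23
    cp_feature_frac: float = 0.8
    antisense_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.gene_length % 3 != 0 or self.gene_length < 9:
            raise ConfigError("gene_length must be >= 9 and divisible by 3")
        if self.insertion_length < 50:
            raise ConfigError("insertion_length must be >= 50 bp")
        p_rest = 1.0 - self.p_nuclear - self.p_mito - self.p_cp
        if p_rest < -1e-9 or min(self.p_nuclear, self.p_mito, self.p_cp) < 0:
            raise ConfigError("read-class proportions must be >= 0 and sum to <= 1")
        if not 0.0 <= self.cp_feature_frac <= 1.0:
            raise ConfigError("cp_feature_frac outside [0,1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigError("error_rate outside [0,1)")

    def read_lengths(self) -> tuple[np.ndarray, np.ndarray]:
        """(lengths, probabilities) of the read-length distribution."""
        if self.length_dist is not None:
            lens = np.array(sorted(self.length_dist), dtype=int)
            probs = np.array([self.length_dist[l] for l in lens], dtype=float)
            probs = probs / probs.sum()
            return lens, probs
        if self.mrna_mode:
            lens = np.arange(50, 151)
        else:
            lens = np.arange(18, 25)
        return lens, np.full(len(lens), 1.0 / len(lens))


@dataclass
class SimulatedReferences:
    refset: ReferenceSet
    insertions: list[tuple[int, int]]  # 1-based inclusive, on nuclear genome
    intergenic: list[tuple[int, int]]  # 1-based inclusive, on cp genome
    edit_sites: list[EditSiteSpec]  # positions resolved
    config: SimConfig


@dataclass
class SimulatedReads:
    reads: list[ReadRecord]
    read_truth: pd.DataFrame
    site_truth: pd.DataFrame


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _random_gene(rng: np.random.Generator, length: int) -> str:
    n_codons = length // 3 - 2
    body = "".join(rng.choice(_ALL_CODONS, size=n_codons))
    return "ATG" + body + "TAA"


def simulate_references(cfg: SimConfig) -> SimulatedReferences:
    """Build the tri-genome reference set with annotation.

    Chloroplast features alternate strands; the nuclear genome receives
    ``insertion_count`` exact chloroplast copies of
    ``insertion_length`` bp; the mitochondrial genome is scrubbed of any
    18-mer shared with the chloroplast genome.
    """
    rng = np.random.default_rng([cfg.seed, 101])

    # --- chloroplast: alternating spacer / feature layout
    features: list[Feature] = []
    gene_seqs: dict[str, str] = {}
    parts: list[str] = []
    cursor = 0
    intergenic: list[tuple[int, int]] = []

    def add_spacer(length: int) -> None:
        nonlocal cursor
        if length <= 0:
            return
        parts.append(_random_seq(rng, length))
        intergenic.append((cursor + 1, cursor + length))
        cursor += length

    names = [f"gene{i+1:02d}" for i in range(cfg.n_genes)] + [
        f"trn{i+1:02d}" for i in range(cfg.n_trnas)
    ]
    kinds = ["CDS"] * cfg.n_genes + ["tRNA"] * cfg.n_trnas
    span_needed = cfg.n_genes * cfg.gene_length + cfg.n_trnas * cfg.trna_length
    n_feat = len(names)
    slack = cfg.cp_length - span_needed
    if slack < (n_feat + 1) * 60:
        raise ConfigError(
            f"cp_length {cfg.cp_length} too small for {n_feat} features "
            f"(span {span_needed} + minimum spacers)"
        )
    spacer = slack // (n_feat + 1)

    for i, (name, kind) in enumerate(zip(names, kinds)):
        add_spacer(spacer)
        if kind == "CDS":
            sense = _random_gene(rng, cfg.gene_length)
            anticodon = None
        else:
            seq = list(_random_seq(rng, cfg.trna_length))
            seq[33] = "A"  # anticodon first base (wobble, position 34)
            seq[34] = "A"  # position 35
            sense = "".join(seq)
            anticodon = sense[33:36]
        strand = "+" if i % 2 == 0 else "-"
        placed = sense if strand == "+" else revcomp(sense)
        start, end = cursor + 1, cursor + len(sense)
        parts.append(placed)
        cursor = end
        features.append(
            Feature(name, kind, "cp_genome", ((start, end),), strand, anticodon)
        )
        gene_seqs[name] = sense
    add_spacer(cfg.cp_length - cursor)
    cp_seq = "".join(parts)
    assert len(cp_seq) == cfg.cp_length

    # --- nuclear genome with plastid insertions
    nuc = list(_random_seq(rng, cfg.nuc_length))
    insertions: list[tuple[int, int]] = []
    if cfg.insertion_count * (cfg.insertion_length + 2) > cfg.nuc_length // 2:
        raise ConfigError("infeasible nuclear insertion packing")
    attempts = 0
    while len(insertions) < cfg.insertion_count:
        attempts += 1
        if attempts > 1000:
            raise ConfigError("could not place nuclear insertions")
        src = int(rng.integers(0, cfg.cp_length - cfg.insertion_length + 1))
        dst = int(rng.integers(0, cfg.nuc_length - cfg.insertion_length + 1))
        # keep copies well separated so shared blocks stay maximal and distinct
        if any(
            abs(dst - (a - 1)) < cfg.insertion_length + 10 for a, _ in insertions
        ):
            continue
        nuc[dst : dst + cfg.insertion_length] = cp_seq[
            src : src + cfg.insertion_length
        ]
        insertions.append((dst + 1, dst + cfg.insertion_length))
    nuc_seq = "".join(nuc)

    # --- mitochondrial genome free of chloroplast 18-mers
    k = 18
    cp_kmers = {cp_seq[i : i + k] for i in range(len(cp_seq) - k + 1)}
    mt = list(_random_seq(rng, cfg.mt_length))
    for _ in range(100):
        mt_seq = "".join(mt)
        dirty = [
            i for i in range(len(mt_seq) - k + 1) if mt_seq[i : i + k] in cp_kmers
        ]
        if not dirty:
            break
        for i in dirty:
            j = i + k // 2
            current = mt[j]
            mt[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[current]
    else:  # pragma: no cover - astronomically unlikely
        raise ConfigError("could not scrub mitochondrial genome of cp 18-mers")
    mt_seq = "".join(mt)

    sequences = [
        ReferenceSequence("cp_genome", cp_seq, "chloroplast"),
        ReferenceSequence("nuc_genome", nuc_seq, "nuclear"),
        ReferenceSequence("mt_genome", mt_seq, "mitochondrial"),
    ]
    for f in features:
        cat = "cds" if f.ftype == "CDS" else "trna"
        sequences.append(ReferenceSequence(f.gene, gene_seqs[f.gene], cat))
    refset = ReferenceSet.build(sequences, features)

    # --- resolve planted edit sites
    resolved: list[EditSiteSpec] = []
    for spec in cfg.edit_sites:
        sense = gene_seqs.get(spec.gene)
        if sense is None:
            raise ConfigError(f"edit site names unknown gene {spec.gene!r}")
        ref_base, _ = _EDIT_BASE[spec.etype]
        if spec.cds_pos is None:
            # interior candidates, away from start/stop codons
            lo, hi = 9, len(sense) - 9
            candidates = [
                p for p in range(lo, hi + 1) if sense[p - 1] == ref_base
            ]
            if not candidates:
                raise ConfigError(f"{spec.gene}: no {ref_base} available to edit")
            pos = int(rng.choice(candidates))
            resolved.append(replace(spec, cds_pos=pos))
        else:
            if sense[spec.cds_pos - 1] != ref_base:
                raise ConfigError(
                    f"{spec.gene}:{spec.cds_pos} is "
                    f"{sense[spec.cds_pos - 1]!r}, not {ref_base!r} "
                    f"required for {spec.etype}"
                )
            resolved.append(spec)

    return SimulatedReferences(refset, insertions, intergenic, resolved, cfg)


# ---------------------------------------------------------------------------
# independent seed-and-verify scan used for truth labelling


def _occurs(haystacks: Sequence[str], needle: str) -> bool:
    return any(needle in h for h in haystacks)


def _within_two_mismatches(read: str, refs: Sequence[str]) -> bool:
    """True iff some forward-strand window is within Hamming distance 2.

    Pigeonhole over three segments; intentionally a separate
    implementation from the mapper module (used only to label truth).
    """
    L = len(read)
    n = 3
    base, rem = divmod(L, n)
    segs = []
    off = 0
    for i in range(n):
        size = base + (1 if i < rem else 0)
        segs.append((off, read[off : off + size]))
        off += size
    for ref in refs:
        if L > len(ref):
            continue
        checked: set[int] = set()
        for off, seg in segs:
            i = ref.find(seg)
            while i != -1:
                start = i - off
                if 0 <= start <= len(ref) - L and start not in checked:
                    checked.add(start)
                    window = ref[start : start + L]
                    d = 0
                    for x, y in zip(read, window):
                        if x != y:
                            d += 1
                            if d > 2:
                                break
                    if d <= 2:
                        return True
                i = ref.find(seg, i + 1)
    return False


def _expected_class(
    seq: str,
    cp_targets: Sequence[str],
    nuclear: str,
    mito: str,
) -> str:
    if _occurs(cp_targets, seq):
        return "cp_m0"
    if seq in nuclear:
        return "nuclear"
    if seq in mito:
        return "mito"
    if _within_two_mismatches(seq, cp_targets):
        return "cp_m2"
    return "unaligned"


def simulate_reads(sim: SimulatedReferences, cfg: Optional[SimConfig] = None) -> SimulatedReads:
    """Draw the read library and its truth table from simulated references."""
    cfg = cfg or sim.config
    rng = np.random.default_rng([cfg.seed, 202])
    refset = sim.refset
    cp_targets = [s.sequence for s in refset.chloroplast_targets()]
    nuc_seq = refset.genome("nuclear").sequence
    mt_seq = refset.genome("mitochondrial").sequence
    cp_seq = refset.genome("chloroplast").sequence
    verify = cfg.error_rate == 0.0

    lens, lprobs = cfg.read_lengths()

    p_feat = cfg.p_cp * cfg.cp_feature_frac
    p_inter = cfg.p_cp * (1.0 - cfg.cp_feature_frac)
    p_unmap = max(0.0, 1.0 - cfg.p_nuclear - cfg.p_mito - cfg.p_cp)
    n_nuc, n_mito, n_feat, n_inter, n_unmap = rng.multinomial(
        cfg.read_count, [cfg.p_nuclear, cfg.p_mito, p_feat, p_inter, p_unmap]
    )

    feats = refset.features
    flens = np.array([f.spliced_length for f in feats], dtype=float)
    fprobs = flens / flens.sum()
    sense_seqs = {f.gene: refset.sequences[f.gene].sequence for f in feats}
    sites_by_gene: dict[str, list[EditSiteSpec]] = {}
    for s in sim.edit_sites:
        sites_by_gene.setdefault(s.gene, []).append(s)

    site_overlap = {(s.gene, s.cds_pos): 0 for s in sim.edit_sites}
    site_edited = {(s.gene, s.cds_pos): 0 for s in sim.edit_sites}

    # nuclear sampling windows avoid insertion intervals (margin = max length)
    max_len = int(lens.max())
    blocked = [(a - max_len, b) for a, b in sim.insertions]
    nuc_starts = np.ones(len(nuc_seq) - max_len + 1, dtype=bool)
    for a, b in blocked:
        nuc_starts[max(0, a - 1) : b] = False
    nuc_start_pool = np.nonzero(nuc_starts)[0]
    if len(nuc_start_pool) == 0:
        raise ConfigError("no nuclear windows outside insertions")

    inter_pool: list[tuple[int, int]] = [
        (a, b) for a, b in sim.intergenic if b - a + 1 >= max_len
    ]
    if n_inter > 0 and not inter_pool:
        raise ConfigError("no intergenic interval long enough for reads")
    inter_w = np.array([b - a + 1 - max_len + 1 for a, b in inter_pool], dtype=float)
    inter_p = inter_w / inter_w.sum() if len(inter_pool) else None

    reads: list[ReadRecord] = []
    truth_rows: list[dict] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"r{counter:07d}"

    def apply_errors(seq: str) -> tuple[str, int]:
        if cfg.error_rate == 0.0:
            return seq, 0
        mask = rng.random(len(seq)) < cfg.error_rate
        if not mask.any():
            return seq, 0
        chars = list(seq)
        for i in np.nonzero(mask)[0]:
            alt = "ACGT".replace(chars[i], "")
            chars[i] = alt[int(rng.integers(0, 3))]
        return "".join(chars), int(mask.sum())

    def emit(seq, origin, ref_id, start, gene, edited_positions, expected):
        rid = next_id()
        reads.append(ReadRecord(rid, seq))
        truth_rows.append(
            {
                "read_id": rid,
                "origin": origin,
                "ref_id": ref_id,
                "start": start,
                "length": len(seq),
                "gene": gene,
                "edited_positions": ";".join(map(str, edited_positions)) or ".",
                "n_errors": 0,
                "expected_class": expected,
            }
        )
        return truth_rows[-1]

    # --- transcript (sense-strand feature) reads
    gene_idx = rng.choice(len(feats), size=n_feat, p=fprobs)
    for gi in gene_idx:
        f = feats[int(gi)]
        sense = sense_seqs[f.gene]
        L = int(rng.choice(lens, p=lprobs))
        L = min(L, len(sense))
        start0 = int(rng.integers(0, len(sense) - L + 1))
        seq = sense[start0 : start0 + L]
        edited: list[int] = []
        for s in sites_by_gene.get(f.gene, []):
            p0 = s.cds_pos - 1
            if start0 <= p0 < start0 + L:
                site_overlap[(s.gene, s.cds_pos)] += 1
                if rng.random() < s.rate:
                    _, alt = _EDIT_BASE[s.etype]
                    seq = seq[: p0 - start0] + alt + seq[p0 - start0 + 1 :]
                    edited.append(s.cds_pos)
                    site_edited[(s.gene, s.cds_pos)] += 1
        seq, n_err = apply_errors(seq)
        if verify:
            if edited:
                expected = _expected_class(seq, cp_targets, nuc_seq, mt_seq)
            else:
                expected = "cp_m0"  # exact copy of the extracted feature
        else:
            expected = ""
        row = emit(seq, "cp_feature", f.gene, start0 + 1, f.gene, edited, expected)
        row["n_errors"] = n_err

    # --- intergenic chloroplast reads (forward strand, strictly intergenic)
    for _ in range(n_inter):
        iv = inter_pool[int(rng.choice(len(inter_pool), p=inter_p))]
        L = int(rng.choice(lens, p=lprobs))
        a, b = iv
        start0 = int(rng.integers(a - 1, b - L + 1))
        seq = cp_seq[start0 : start0 + L]
        seq, n_err = apply_errors(seq)
        expected = "cp_m0" if verify else ""
        row = emit(seq, "cp_intergenic", "cp_genome", start0 + 1, ".", [], expected)
        row["n_errors"] = n_err

    # --- nuclear background (outside insertions)
    for _ in range(n_nuc):
        L = int(rng.choice(lens, p=lprobs))
        while True:
            start0 = int(nuc_start_pool[rng.integers(0, len(nuc_start_pool))])
            seq = nuc_seq[start0 : start0 + L]
            if not verify or not _occurs(cp_targets, seq):
                break
        seq, n_err = apply_errors(seq)
        expected = "nuclear" if verify else ""
        row = emit(seq, "nuclear", "nuc_genome", start0 + 1, ".", [], expected)
        row["n_errors"] = n_err

    # --- mitochondrial background
    for _ in range(n_mito):
        L = int(rng.choice(lens, p=lprobs))
        while True:
            start0 = int(rng.integers(0, len(mt_seq) - L + 1))
            seq = mt_seq[start0 : start0 + L]
            if not verify or (
                not _occurs(cp_targets, seq) and seq not in nuc_seq
            ):
                break
        seq, n_err = apply_errors(seq)
        expected = "mito" if verify else ""
        row = emit(seq, "mito", "mt_genome", start0 + 1, ".", [], expected)
        row["n_errors"] = n_err

    # --- unmappable reads (verified >2 mismatches from everything)
    for _ in range(n_unmap):
        L = int(rng.choice(lens, p=lprobs))
        while True:
            seq = _random_seq(rng, L)
            if not verify:
                break
            if _expected_class(seq, cp_targets, nuc_seq, mt_seq) == "unaligned":
                break
        seq, n_err = apply_errors(seq)
        expected = "unaligned" if verify else ""
        row = emit(seq, "unmappable", ".", 0, ".", [], expected)
        row["n_errors"] = n_err

    # shuffle emission order (ids stay attached to their truth rows)
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    read_truth = pd.DataFrame([truth_rows[i] for i in order])

    site_truth = pd.DataFrame(
        [
            {
                "gene": s.gene,
                "cds_pos": s.cds_pos,
                "etype": s.etype,
                "true_rate": s.rate,
                "n_reads_overlapping": site_overlap[(s.gene, s.cds_pos)],
                "n_reads_edited": site_edited[(s.gene, s.cds_pos)],
            }
            for s in sim.edit_sites
        ],
        columns=[
            "gene",
            "cds_pos",
            "etype",
            "true_rate",
            "n_reads_overlapping",
            "n_reads_edited",
        ],
    )
    return SimulatedReads(reads, read_truth, site_truth)


def plant_central_sites(
    cfg: SimConfig, rates: Sequence[float], etype: str = "C2U"
) -> SimConfig:
    """Return a config with one edit site per CDS gene, at the editable base
    nearest the gene midpoint.

    Central placement maximises overlapping-read counts (sites near gene
    ends are covered by roughly half as many reads), which is what
    parameter-recovery studies at a prescribed coverage want.
    """
    base_cfg = replace(cfg, edit_sites=())
    sim = simulate_references(base_cfg)
    genes = [f.gene for f in sim.refset.features if f.ftype == "CDS"]
    if len(rates) > len(genes):
        raise ConfigError(f"{len(rates)} rates but only {len(genes)} genes")
    ref_base, _ = _EDIT_BASE[etype]
    sites = []
    for gene, rate in zip(genes, rates):
        sense = sim.refset.sequences[gene].sequence
        mid = len(sense) // 2
        candidates = [i + 1 for i, b in enumerate(sense) if b == ref_base]
        if not candidates:
            raise ConfigError(f"{gene}: no {ref_base} to edit")
        pos = min(candidates, key=lambda p: abs(p - mid))
        sites.append(EditSiteSpec(gene, pos, rate, etype))
    return replace(cfg, edit_sites=tuple(sites))


def write_simulation(
    sim: SimulatedReferences,
    simreads: SimulatedReads,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write FASTA references, annotation (TSV + GFF3), FASTQ reads and
    truth tables; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refset = sim.refset
    paths = {
        "cp_genome": outdir / "cp_genome.fasta",
        "nuclear": outdir / "nuclear.fasta",
        "mito": outdir / "mito.fasta",
        "cds": outdir / "cds.fasta",
        "trna": outdir / "trna.fasta",
        "annotation": outdir / "annotation.tsv",
        "annotation_gff3": outdir / "annotation.gff3",
        "reads": outdir / "reads.fastq",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_reads": outdir / "truth_reads.tsv",
        "config": outdir / "sim_config.json",
    }
    refio.write_fasta(refset.by_category("chloroplast"), paths["cp_genome"])
    refio.write_fasta(refset.by_category("nuclear"), paths["nuclear"])
    refio.write_fasta(refset.by_category("mitochondrial"), paths["mito"])
    refio.write_fasta(refset.by_category("cds"), paths["cds"])
    refio.write_fasta(refset.by_category("trna"), paths["trna"])
    refio.write_annotation_tsv(refset.features, paths["annotation"])
    refio.write_annotation_gff3(refset.features, paths["annotation_gff3"])
    refio.write_fastq(simreads.reads, paths["reads"])
    simreads.site_truth.to_csv(paths["truth_sites"], sep="\t", index=False)
    simreads.read_truth.to_csv(paths["truth_reads"], sep="\t", index=False)
    cfg_dict = asdict(sim.config)
    cfg_dict["edit_sites"] = [asdict(s) for s in sim.edit_sites]
    with open(paths["config"], "w") as fh:
        json.dump(cfg_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
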