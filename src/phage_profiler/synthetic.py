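"""Synthetic phage communities with planted ground truth.

Generates genome sets organised into clusters of known nucleotide divergence
plus unrelated singletons, per-genome protein-domain hit tables drawn from
cluster-specific domain pools, and sequencing reads that carry the coverage
signatures of the phage's packaging strategy:

* ``DTR`` virions are ``repeat + core + repeat``; mapping their reads onto
  the unit genome (repeat represented once) doubles the depth over the
  repeat, with single-base-sharp steps at both repeat boundaries.
* ``HEADFUL_PAC`` virions are terminally redundant circular permutations; a
  configurable fraction of packaging events starts exactly at the *pac*
  site, producing a read-start pileup at a single position while the other
  genome end stays variable.
* ``NONE`` is the negative control: reads drawn uniformly from the circular
  genome, with no termini structure at all.

Reads are produced by a fragmentation model of the sequencing library: each
packaged DNA molecule is sheared at Poisson-distributed breakpoints, and one
read is taken off each end of every fragment long enough to sequence.
Because the molecule's physical ends are themselves fragment boundaries,
read starts pile up exactly at the termini and coverage stays flat right up
to them -- this is the library-preparation feature that makes genome termini
visible in coverage data at single-base resolution.

All randomness flows from a single seed through per-operation derived
streams; identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from .domains import ClusterAssignment, DomainHit
from .genome_io import PhageGenomeRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def seq_to_codes(sequence: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return arr


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# specifications


@dataclass
class ClusterSpec:
    """One planted cluster: an ancestor genome plus diverged variants."""

    n_genomes: int
    ancestor_length: int
    gc_target: float
    within_cluster_substitution_rate: float
    domain_pool_size: int
    domains_per_genome: int

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("each cluster needs n_genomes >= 1")
        if self.ancestor_length <= 0:
            raise ValueError("ancestor_length must be positive")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError("gc_target must be in [0, 1]")
        if not 0.0 <= self.within_cluster_substitution_rate < 1.0:
            raise ValueError("substitution rate must be in [0, 1)")
        if self.domains_per_genome > self.domain_pool_size:
            raise ValueError("domains_per_genome exceeds domain_pool_size")


@dataclass
class CommunitySpec:
    """A community: clusters of related genomes plus unrelated singletons.

    Defaults emulate a small actinophage community: genomes of 35-140 kb
    with GC between 45 and 75%, within-cluster relatedness around 98% ANI,
    and one highly divergent singleton with a private domain repertoire.
    """

    clusters: list[ClusterSpec]
    n_singletons: int = 1
    shared_domain_fraction: float = 0.0
    seed: int = 0
    singleton_length: int = 47000
    singleton_gc: float = 0.69
    singleton_domains_per_genome: int = 12

    def validate(self) -> None:
        if not self.clusters:
            raise ValueError("community needs at least one cluster")
        for c in self.clusters:
            c.validate()
        if self.n_singletons < 0:
            raise ValueError("n_singletons must be >= 0")
        if not 0.0 <= self.shared_domain_fraction <= 1.0:
            raise ValueError("shared_domain_fraction must be in [0, 1]")


def default_community_spec(seed: int = 0) -> CommunitySpec:
    """Three clusters of three genomes plus one singleton (Table-2-like sizes)."""
    return CommunitySpec(
        clusters=[
            ClusterSpec(3, 39000, 0.72, 0.02, 25, 15),
            ClusterSpec(3, 49000, 0.66, 0.02, 25, 15),
            ClusterSpec(3, 57000, 0.48, 0.02, 25, 15),
        ],
        n_singletons=1,
        shared_domain_fraction=0.0,
        seed=seed,
    )


@dataclass
class TerminiModel:
    """Virion architecture controlling the simulated coverage signature."""

    kind: str  # "DTR", "HEADFUL_PAC" or "NONE"
    repeat_length: int | None = None
    pac_position: int | None = None
    terminal_redundancy: int | None = None

    def validate(self, genome_length: int) -> None:
        if self.kind == "DTR":
            if self.repeat_length is None:
                raise ValueError("DTR model requires repeat_length")
            if not 0 < self.repeat_length < genome_length / 2:
                raise ValueError("repeat_length must be < genome length / 2")
        elif self.kind == "HEADFUL_PAC":
            if self.pac_position is None:
                raise ValueError("HEADFUL_PAC model requires pac_position")
            if not 0 <= self.pac_position < genome_length:
                raise ValueError("pac_position must lie within the genome")
            tr = self.terminal_redundancy
            if tr is not None and not 0 <= tr < genome_length / 4:
                raise ValueError("terminal_redundancy out of range")
        elif self.kind != "NONE":
            raise ValueError(f"unknown termini model kind: {self.kind!r}")


class Read(NamedTuple):
    id: str
    sequence: str
    true_origin: tuple[int, int]  # 0-based unit-genome interval; end may
    # exceed the genome length to denote wrap-around on the circle
    strand: str


@dataclass
class ReadSet:
    """Simulated single-end reads with per-read true origins."""

    ids: list[str]
    sequences: list[str]
    origins: list[tuple[int, int]]
    strands: list[str]
    read_length: int
    error_rate: float
    target_depth: float
    genome_length: int

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[Read]:
        for i in range(len(self.ids)):
            yield Read(self.ids[i], self.sequences[i], self.origins[i], self.strands[i])

    def total_bases(self) -> int:
        return len(self.ids) * self.read_length

    def true_coverage(self) -> np.ndarray:
        """Per-base depth from the true origins, folded onto the unit genome."""
        depth = np.zeros(self.genome_length, dtype=np.int64)
        L = self.genome_length
        for start, end in self.origins:
            if end <= L:
                depth[start:end] += 1
            else:
                depth[start:] += 1
                depth[: end - L] += 1
        return depth

    def true_start_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-base 5' read-start counts (forward, reverse) from true origins."""
        fwd = np.zeros(self.genome_length, dtype=np.int64)
        rev = np.zeros(self.genome_length, dtype=np.int64)
        L = self.genome_length
        for (start, end), strand in zip(self.origins, self.strands):
            if strand == "+":
                fwd[start % L] += 1
            else:
                rev[(end - 1) % L] += 1
        return fwd, rev


# ---------------------------------------------------------------------------
# genome-level operations


def generate_genome(length: int, gc_target: float, seed: int) -> str:
    """I.i.d. random genome with P(G)=P(C)=gc_target/2."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc_target <= 1.0:
        raise ValueError("gc_target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p_at = (1.0 - gc_target) / 2.0
    p_gc = gc_target / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return codes_to_seq(codes.astype(np.uint8))


def evolve_variant(
    parent: str,
    substitution_rate: float,
    seed: int,
    indel_rate: float = 0.0,
) -> str:
    """Substitute each base independently with the given probability.

    A substituted base is replaced by a uniformly chosen *different* base, so
    the expected Hamming-difference fraction equals ``substitution_rate``
    exactly.  Small indels can be switched on via ``indel_rate`` (off by
    default, which keeps the mapping from planted divergence to expected ANI
    analytic).
    """
    if not 0.0 <= substitution_rate < 1.0:
        raise ValueError("substitution_rate must be in [0, 1)")
    if not 0.0 <= indel_rate < 1.0:
        raise ValueError("indel_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    codes = seq_to_codes(parent)
    mask = rng.random(codes.size) < substitution_rate
    shifts = rng.integers(1, 4, size=int(mask.sum()))
    codes = codes.copy()
    codes[mask] = (codes[mask] + shifts) % 4
    if indel_rate > 0.0:
        keep = rng.random(codes.size) >= indel_rate / 2.0
        codes = codes[keep]
        ins_mask = rng.random(codes.size) < indel_rate / 2.0
        if ins_mask.any():
            pieces = []
            last = 0
            for pos in np.flatnonzero(ins_mask):
                pieces.append(codes[last : pos + 1])
                pieces.append(rng.integers(0, 4, size=1).astype(np.uint8))
                last = pos + 1
            pieces.append(codes[last:])
            codes = np.concatenate(pieces)
    return codes_to_seq(codes.astype(np.uint8))


def _domain_pools(spec: CommunitySpec, rng: np.random.Generator):
    """Cluster and singleton accession pools, synthetic Pfam-style names."""
    shared_n = int(round(spec.shared_domain_fraction * min(c.domain_pool_size for c in spec.clusters))) if spec.clusters else 0
    shared = [f"PF8{j:04d}" for j in range(shared_n)]
    cluster_pools = []
    for i, c in enumerate(spec.clusters):
        private = [f"PF9{i:01d}{j:03d}" for j in range(c.domain_pool_size - shared_n)]
        cluster_pools.append(shared + private)
    singleton_pools = []
    for j in range(spec.n_singletons):
        singleton_pools.append(
            [f"PF7{j:01d}{k:03d}" for k in range(max(spec.singleton_domains_per_genome * 2, 8))]
        )
    return cluster_pools, singleton_pools


def _domain_hits_for_genome(
    genome_id: str,
    pool: Sequence[str],
    n_domains: int,
    rng: np.random.Generator,
) -> list[DomainHit]:
    chosen = sorted(rng.choice(len(pool), size=n_domains, replace=False))
    hits = []
    protein = 0
    for idx in chosen:
        acc = pool[idx]
        n_copies = 2 if rng.random() < 0.1 else 1  # occasional multi-protein domain
        for _ in range(n_copies):
            protein += 1
            evalue = 10.0 ** (-rng.uniform(4.0, 30.0))
            bitscore = float(np.round(rng.uniform(50.0, 500.0), 1))
            hits.append(
                DomainHit(
                    genome_id=genome_id,
                    protein_id=f"{genome_id}_p{protein:04d}",
                    domain_accession=acc,
                    domain_name=f"SynDom_{acc}",
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
    return hits


def plant_community(
    spec: CommunitySpec,
) -> tuple[list[PhageGenomeRecord], dict[str, list[DomainHit]], ClusterAssignment]:
    """Generate genomes, domain tables and truth labels for a community.

    Each cluster is one ancestor plus independently diverged variants; each
    singleton is an unrelated genome with a private domain pool.  Truth
    labels are ``C1..Ck`` for clusters and ``S1..Sm`` for singletons.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    genome_ss, domain_ss = root.spawn(2)
    genome_rng_seeds = genome_ss.generate_state(2 * sum(c.n_genomes for c in spec.clusters) + spec.n_singletons + len(spec.clusters))
    domain_rng = np.random.default_rng(domain_ss)

    cluster_pools, singleton_pools = _domain_pools(spec, domain_rng)

    records: list[PhageGenomeRecord] = []
    tables: dict[str, list[DomainHit]] = {}
    labels: dict[str, str] = {}
    singletons: set[str] = set()

    seed_i = 0

    def next_seed() -> int:
        nonlocal seed_i
        s = int(genome_rng_seeds[seed_i]) % (2**31)
        seed_i += 1
        return s

    for ci, cluster in enumerate(spec.clusters):
        label = f"C{ci + 1}"
        ancestor = generate_genome(cluster.ancestor_length, cluster.gc_target, next_seed())
        for gi in range(cluster.n_genomes):
            gid = f"{label}_g{gi + 1}"
            seq = evolve_variant(ancestor, cluster.within_cluster_substitution_rate, next_seed())
            records.append(PhageGenomeRecord(id=gid, sequence=seq, truth_cluster=label))
            tables[gid] = _domain_hits_for_genome(
                gid, cluster_pools[ci], cluster.domains_per_genome, domain_rng
            )
            labels[gid] = label
    for si in range(spec.n_singletons):
        label = f"S{si + 1}"
        gid = f"{label}_g1"
        seq = generate_genome(spec.singleton_length, spec.singleton_gc, next_seed())
        records.append(PhageGenomeRecord(id=gid, sequence=seq, truth_cluster=label))
        tables[gid] = _domain_hits_for_genome(
            gid, singleton_pools[si], spec.singleton_domains_per_genome, domain_rng
        )
        labels[gid] = label
        singletons.add(gid)

    return records, tables, ClusterAssignment(labels=labels, singletons=singletons)


# ---------------------------------------------------------------------------
# read simulation


def _fragment_reads(
    mol: np.ndarray,
    rng: np.random.Generator,
    read_length: int,
    mean_fragment: float,
    circular_length: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fragment one molecule; return (fwd_starts, rev_ends) in molecule coords.

    For a linear molecule both physical ends act as fragment boundaries; for
    ``circular_length`` set, the molecule is a circle of that length and
    fragment boundaries are breakpoints only.
    """
    if circular_length is None:
        m = mol.size
        pos = np.flatnonzero(rng.random(m - 1) < 1.0 / mean_fragment) + 1
        bounds = np.concatenate(([0], pos, [m]))
        lens = np.diff(bounds)
        keep = lens >= read_length
        return bounds[:-1][keep], bounds[1:][keep]
    L = circular_length
    pos = np.flatnonzero(rng.random(L) < 1.0 / mean_fragment)
    if pos.size < 2:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    starts = pos
    ends = np.concatenate((pos[1:], [pos[0] + L]))
    keep = (ends - starts) >= read_length
    return starts[keep], ends[keep]


def simulate_packaged_reads(
    genome: str,
    model: TerminiModel,
    target_depth: float,
    read_length: int,
    error_rate: float,
    seed: int,
    fixed_start_fraction: float = 0.5,
    mean_fragment_length: float | None = None,
) -> ReadSet:
    """Simulate single-end reads from packaged virion DNA.

    Each virion molecule is sheared at Poisson breakpoints (mean fragment
    length defaults to twice the read length) and one read is taken off each
    end of every fragment at least one read long.  Molecule ends are
    fragment boundaries, so termini leave single-base coverage / read-start
    signatures; interior read starts are approximately uniform.

    ``fixed_start_fraction`` applies to HEADFUL_PAC only: the fraction of
    packaging events whose molecule starts exactly at the *pac* site (the
    remainder start uniformly on the circle, emulating downstream headfuls
    of a processive series).
    """
    L = len(genome)
    if read_length >= L:
        raise ValueError("read_length must be smaller than the genome")
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    model.validate(L)
    rng = np.random.default_rng(seed)
    F = float(mean_fragment_length) if mean_fragment_length else 2.0 * read_length
    if F < read_length:
        raise ValueError("mean fragment length must be >= read length")

    codes = seq_to_codes(genome)
    doubled = np.concatenate((codes, codes))
    tripled = np.concatenate((doubled, codes))  # headful molecules can span > 2 genome lengths from a late start
    rl = read_length

    # molecule plan: list of (offset_on_unit_genome, molecule_array, circular_length)
    if model.kind == "DTR":
        R = model.repeat_length
        virion = np.concatenate((codes, codes[:R]))
        ref_len = L + R  # depth accounted relative to virion length
        mean_mol = float(ref_len)
    elif model.kind == "HEADFUL_PAC":
        tr = model.terminal_redundancy if model.terminal_redundancy is not None else int(round(0.04 * L))
        ref_len = L
        mean_mol = float(L + tr)
    else:  # NONE
        ref_len = L
        mean_mol = float(L)

    reads_per_copy = 2.0 * (mean_mol / F) * math.exp(-rl / F)
    n_copies = max(1, int(round(target_depth * ref_len / (rl * reads_per_copy))))

    fwd_chunks: list[np.ndarray] = []
    rev_chunks: list[np.ndarray] = []
    fwd_origins: list[np.ndarray] = []
    rev_origins: list[np.ndarray] = []
    ar = np.arange(rl)

    for copy in range(n_copies):
        if model.kind == "DTR":
            offset = 0
            mol = virion
            starts, ends = _fragment_reads(mol, rng, rl, F)
        elif model.kind == "HEADFUL_PAC":
            if rng.random() < fixed_start_fraction:
                start = model.pac_position
            else:
                start = int(rng.integers(0, L))
            tr = model.terminal_redundancy if model.terminal_redundancy is not None else int(round(0.04 * L))
            # capsid fill varies between packaging events: the genome end is
            # variable, so the terminally redundant segment of each molecule
            # decays smoothly instead of stacking into a repeat-like plateau
            mlen = L + int(rng.integers(0, 2 * tr + 1))
            offset = start
            mol = tripled[start : start + mlen]
            starts, ends = _fragment_reads(mol, rng, rl, F)
        else:
            offset = 0
            mol = doubled
            starts, ends = _fragment_reads(mol, rng, rl, F, circular_length=L)
        if starts.size:
            fwd_chunks.append(mol[starts[:, None] + ar])
            rev_chunks.append(3 - mol[(ends - 1)[:, None] - ar])
            fwd_origins.append((offset + starts) % L)
            rev_origins.append((offset + ends - rl) % L)

    if fwd_chunks:
        fwd_mat = np.vstack(fwd_chunks)
        rev_mat = np.vstack(rev_chunks)
        fwd_o = np.concatenate(fwd_origins)
        rev_o = np.concatenate(rev_origins)
    else:  # degenerate: no fragments long enough
        fwd_mat = rev_mat = np.zeros((0, rl), dtype=np.uint8)
        fwd_o = rev_o = np.empty(0, dtype=np.int64)

    mat = np.vstack((fwd_mat, rev_mat)).astype(np.uint8)
    n_fwd = fwd_mat.shape[0]
    n = mat.shape[0]
    if error_rate > 0.0 and n:
        err = rng.random(mat.shape) < error_rate
        shifts = rng.integers(1, 4, size=int(err.sum()))
        mat[err] = (mat[err] + shifts) % 4

    ascii_mat = _BASES[mat]
    raw = ascii_mat.tobytes()
    sequences = [raw[i * rl : (i + 1) * rl].decode() for i in range(n)]
    origins = [(int(s), int(s) + rl) for s in fwd_o] + [(int(s), int(s) + rl) for s in rev_o]
    strands = ["+"] * n_fwd + ["-"] * (n - n_fwd)
    ids = [f"r{i:07d}" for i in range(n)]
    return ReadSet(
        ids=ids,
        sequences=sequences,
        origins=origins,
        strands=strands,
        read_length=rl,
        error_rate=error_rate,
        target_depth=target_depth,
        genome_length=L,
    )


# ---------------------------------------------------------------------------
# plain-text writers


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    """Write reads as FASTQ with a constant quality string."""
    qual = "I" * readset.read_length
    with open(path, "w") as fh:
        for read in readset:
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def write_read_truth(readset: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\torigin_start\torigin_end\tstrand\n")
        for read in readset:
            s, e = read.true_origin
            fh.write(f"{read.id}\t{s}\t{e}\t{read.strand}\n")


def write_cluster_truth(truth: ClusterAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tcluster\tis_singleton\n")
        for gid in sorted(truth.labels):
            fh.write(f"{gid}\t{truth.labels[gid]}\t{int(gid in truth.singletons)}\n")


def write_domain_table(hits: Sequence[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tprotein_id\tdomain_accession\tdomain_name\tevalue\tbitscore\n")
        for h in hits:
            fh.write(
                f"{h.genome_id}\t{h.protein_id}\t{h.domain_accession}\t"
                f"{h.domain_name}\t{h.evalue:.3e}\t{h.bitscore}\n"
            )
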