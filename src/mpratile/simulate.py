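"""Synthetic data generation with full truth records.

Everything the downstream stages consume can be fabricated here: UTR sequences
with planted A/G-rich localization elements, per-oligo count matrices with
replicate structure and negative-binomial noise, and error-bearing paired-end
FASTQ reads.

All randomness flows from a single seed: each public operation derives
independent child generators via ``numpy``'s ``SeedSequence.spawn``-style
seeding (``default_rng(seed)`` per operation, with documented sub-streams), so
identical parameters reproduce byte-identical outputs.

Read geometry mirrors the targeted-sequencing protocol: the forward read is
the first ``fwd_len`` nt of the oligo, the reverse read is a random UMI
followed by the reverse complement of the oligo 3' end (``rev_len`` nt).
Deletions are applied before mutations; after a deletion the read is extended
from the template so reads are always emitted at full declared length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seq import array_to_seq, open_text, revcomp, seq_to_array
from .design import MetaUTR, OligoRecord
from .quantify import CountMatrix, Sample

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ReadSimParams:
    n_reads: int
    fwd_len: int = 97
    rev_len: int = 91
    mutation_rate: float = 0.002
    deletion_rate: float = 0.0001
    umi_len: int = 8
    seed: int = 0
    fwd_adapter: str = ""  # optionally prepended, for exercising trimming
    rev_adapter: str = ""

    def __post_init__(self):
        for rate in (self.mutation_rate, self.deletion_rate):
            if not 0.0 <= rate <= 1.0:
                raise SimulationError("error rates must be in [0, 1]")


@dataclass(frozen=True)
class ElementSpec:
    """A planted localization element within one simulated UTR."""

    gene_id: str
    start: int  # UTR coordinates, 0-based end-exclusive
    end: int
    log2_effect: float

    def __post_init__(self):
        if self.end <= self.start:
            raise SimulationError("element interval must be non-empty")
        if not np.isfinite(self.log2_effect):
            raise SimulationError("log2_effect must be finite")


@dataclass(frozen=True)
class CountSimParams:
    n_genes: int
    utr_len_range: tuple[int, int] = (500, 5000)
    n_replicates: int = 4
    element_spec: tuple[ElementSpec, ...] = ()
    dispersion: float = 0.05
    library_size_range: tuple[float, float] = (5e5, 1.5e6)
    seed: int = 0
    element_ag_fraction: float = 0.8
    flank_len: int = 260
    abundance_sigma: float = 0.5
    min_element_overlap: float = 0.5  # fraction of element an oligo must cover


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside simulated artifacts."""

    read_to_oligo: dict[str, str] = field(default_factory=dict)
    abundances: dict[str, float] = field(default_factory=dict)
    log2_effects: dict[str, float] = field(default_factory=dict)

    def to_jsonl(self, path: str | Path) -> None:
        with open_text(path, "wt") as fh:
            for oid, ab in self.abundances.items():
                fh.write(
                    json.dumps(
                        {
                            "oligo_id": oid,
                            "abundance": ab,
                            "log2_effect": self.log2_effects.get(oid, 0.0),
                        }
                    )
                    + "\n"
                )
            for name, oid in self.read_to_oligo.items():
                fh.write(json.dumps({"read": name, "oligo_id": oid}) + "\n")


# ---------------------------------------------------------------------------
# UTR simulation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int, ag_fraction: float = 0.5) -> str:
    """Random sequence with a target A+G fraction (A/G and C/T equiprobable
    within their halves)."""
    p = np.array(
        [ag_fraction / 2, (1 - ag_fraction) / 2, ag_fraction / 2, (1 - ag_fraction) / 2]
    )
    return array_to_seq(rng.choice(_BASES, size=n, p=p))


def simulate_utrs(params: CountSimParams) -> tuple[list[MetaUTR], list[ElementSpec]]:
    """Generate random UTR sequences with planted A/G-rich elements.

    UTR lengths are uniform over ``utr_len_range``. Background composition is
    uniform (A+G = 0.5); planted element intervals are resampled at
    ``element_ag_fraction``. Flanks of ``flank_len`` random nt are attached so
    pools can be tiled with full end coverage.
    """
    rng = np.random.default_rng(params.seed)
    metas: list[MetaUTR] = []
    lengths = rng.integers(
        params.utr_len_range[0], params.utr_len_range[1] + 1, size=params.n_genes
    )
    by_gene: dict[str, list[ElementSpec]] = {}
    for el in params.element_spec:
        by_gene.setdefault(el.gene_id, []).append(el)
    for g in range(params.n_genes):
        gene_id = f"simgene{g + 1:04d}"
        n = int(lengths[g])
        seq = list(_random_seq(rng, n))
        for el in by_gene.get(gene_id, []):
            if el.end > n:
                raise SimulationError(
                    f"element [{el.start},{el.end}) exceeds UTR length {n} "
                    f"for {gene_id}"
                )
            seq[el.start : el.end] = _random_seq(
                rng, el.end - el.start, params.element_ag_fraction
            )
        metas.append(
            MetaUTR(
                gene_id=gene_id,
                sequence="".join(seq),
                upstream_flank=_random_seq(rng, params.flank_len),
                downstream_flank=_random_seq(rng, params.flank_len),
            )
        )
    return metas, list(params.element_spec)


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------


def _oligo_effect(
    rec: OligoRecord, elements: Sequence[ElementSpec], min_overlap: float, oligo_len: int
) -> float:
    """log2 effect an oligo inherits from planted elements (max over elements
    covering at least ``min_overlap`` of the element)."""
    effect = 0.0
    for el in elements:
        if el.gene_id != rec.gene_id:
            continue
        lo = max(rec.offset, el.start)
        hi = min(rec.offset + oligo_len, el.end)
        if hi - lo >= min_overlap * (el.end - el.start):
            effect = max(effect, el.log2_effect, key=abs)
    return effect


def simulate_counts(
    pool: Sequence[OligoRecord],
    elements: Sequence[ElementSpec],
    params: CountSimParams,
) -> tuple[CountMatrix, SimulationTruth]:
    """Draw a soma/neurite count matrix with planted effects.

    Baseline relative abundances are log-normal. In neurite samples, an oligo
    overlapping a planted element by at least ``min_element_overlap`` of the
    element's length has its abundance multiplied by ``2**log2_effect``;
    per-sample abundances are renormalized to sum to one. Counts are
    NB(mean = abundance x library size, dispersion); the dispersion -> 0
    limit falls back to Poisson draws.
    """
    rng = np.random.default_rng(params.seed + 1)  # sub-stream: counts
    n = len(pool)
    if n == 0:
        raise SimulationError("empty pool")
    olen = len(pool[0].insert_sequence)
    base = np.exp(rng.normal(0.0, params.abundance_sigma, size=n))
    soma_p = base / base.sum()
    effects = np.array(
        [_oligo_effect(r, elements, params.min_element_overlap, olen) for r in pool]
    )
    neur = base * np.exp2(effects)
    neur_p = neur / neur.sum()

    samples = [
        Sample(f"{comp}_{r + 1}", comp, r + 1)
        for comp in ("soma", "neurite")
        for r in range(params.n_replicates)
    ]
    counts = np.zeros((n, len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        lib = rng.uniform(*params.library_size_range)
        p = soma_p if sample.compartment == "soma" else neur_p
        mu = p * lib
        if params.dispersion < 1e-8:
            counts[:, j] = rng.poisson(mu)
        else:
            shape = 1.0 / params.dispersion
            counts[:, j] = rng.poisson(rng.gamma(shape, mu / shape))
    truth = SimulationTruth(
        abundances={r.oligo_id: float(p) for r, p in zip(pool, soma_p)},
        log2_effects={r.oligo_id: float(e) for r, e in zip(pool, effects)},
    )
    return CountMatrix([r.oligo_id for r in pool], samples, counts), truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _apply_errors(
    template: np.ndarray,
    out_len: int,
    rng: np.random.Generator,
    mutation_rate: float,
    deletion_rate: float,
) -> np.ndarray:
    """Emit ``out_len`` bases from ``template`` with per-base deletions applied
    first, then substitutions; the read is refilled from the template after
    deletions so it always reaches full length."""
    window = min(len(template), out_len + 8)
    if deletion_rate > 0:
        keep = rng.random(window) >= deletion_rate
        bases = template[:window][keep][:out_len]
    else:
        bases = template[:out_len].copy()
    if len(bases) < out_len:  # template exhausted by deletions: N-pad (rare)
        bases = np.concatenate(
            [bases, np.full(out_len - len(bases), ord("N"), dtype=np.uint8)]
        )
    bases = np.array(bases, dtype=np.uint8)
    if mutation_rate > 0:
        hit = np.nonzero(rng.random(out_len) < mutation_rate)[0]
        for i in hit:
            choices = _BASES[_BASES != bases[i]]
            bases[i] = choices[rng.integers(len(choices))]
    return bases


def simulate_reads(
    pool: Sequence[OligoRecord],
    abundances: np.ndarray | Sequence[float] | None,
    params: ReadSimParams,
    r1_path: str | Path,
    r2_path: str | Path,
) -> SimulationTruth:
    """Write an error-bearing paired FASTQ and return the truth mapping.

    The source oligo of each pair is drawn from ``abundances`` (uniform when
    ``None``). Quality strings are constant ('I').
    """
    rng = np.random.default_rng(params.seed + 2)  # sub-stream: reads
    n = len(pool)
    olen = min(len(r.insert_sequence) for r in pool)
    if params.fwd_len > olen or params.rev_len > olen:
        raise SimulationError(
            f"read length exceeds oligo length {olen} "
            f"(fwd={params.fwd_len}, rev={params.rev_len})"
        )
    if abundances is None:
        p = np.full(n, 1.0 / n)
    else:
        p = np.asarray(abundances, dtype=float)
        p = p / p.sum()
    fwd_templates = [seq_to_array(r.insert_sequence) for r in pool]
    rc_templates = [seq_to_array(revcomp(r.insert_sequence)) for r in pool]

    sources = rng.choice(n, size=params.n_reads, p=p)
    truth = SimulationTruth(
        abundances={r.oligo_id: float(x) for r, x in zip(pool, p)}
    )
    q1 = "I" * params.fwd_len
    q2 = "I" * (params.umi_len + params.rev_len)
    with open_text(r1_path, "wt") as o1, open_text(r2_path, "wt") as o2:
        for i, src in enumerate(sources):
            name = f"read_{i:07d}"
            fwd = _apply_errors(
                fwd_templates[src], params.fwd_len, rng,
                params.mutation_rate, params.deletion_rate,
            )
            rev = _apply_errors(
                rc_templates[src], params.rev_len, rng,
                params.mutation_rate, params.deletion_rate,
            )
            umi = array_to_seq(_BASES[rng.integers(0, 4, size=params.umi_len)])
            s1 = params.fwd_adapter + array_to_seq(fwd)
            s2 = params.rev_adapter + umi + array_to_seq(rev)
            o1.write(f"@{name}\n{s1}\n+\n{'I' * len(s1)}\n")
            o2.write(f"@{name}\n{s2}\n+\n{'I' * len(s2)}\n")
            truth.read_to_oligo[name] = pool[src].oligo_id
    return truth
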