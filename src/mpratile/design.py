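"""Oligo pool design: meta-UTR construction, gene filters and dense tiling.

The design substrate for a gene is its *meta-UTR*: the positional merge of the
3' UTRs of all filter-passing transcript isoforms, extended on both sides by
``flank_extension`` nucleotides of adjacent genomic sequence so that the UTR
ends are covered by as many oligos as interior positions. Oligos of
``oligo_length`` nt are placed every ``step`` nt along the extended design
sequence; with the defaults (260 nt / 4 nt) every interior UTR nucleotide lands
in exactly 65 distinct oligos.

Coordinates are 0-based, end-exclusive. Oligo offsets are reported relative to
UTR position 0, so the first oligo of a fully flanked design has offset
``-flank_extension``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import normalize_alphabet, revcomp, write_fasta

logger = logging.getLogger(__name__)

#: Annotation tags marking transcripts whose 3' end is not well defined;
#: such transcripts never contribute to a meta-UTR.
EXCLUDED_TAGS = frozenset({"cds_end_NF", "mRNA_end_NF"})

#: Maximum distance (nt) between a gene's polyA site and a conserved polyA
#: site for the gene to pass the conservation filter.
POLYA_CONSERVATION_WINDOW = 200


class DesignError(ValueError):
    """Raised when design inputs violate a contract."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript's 3' UTR as a single genomic interval."""

    transcript_id: str
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str
    tags: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise DesignError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise DesignError(
                f"invalid interval [{self.start}, {self.end}) for {self.transcript_id}"
            )

    @property
    def polya_site(self) -> int:
        """Genomic coordinate of the transcript 3' end (cleavage site)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class MetaUTR:
    """Merged 3' UTR of one gene plus its genomic flanks."""

    gene_id: str
    sequence: str
    upstream_flank: str
    downstream_flank: str
    source_transcripts: list[str] = field(default_factory=list)
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    polya_site: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DesignParams:
    """Tiling geometry and handle configuration."""

    oligo_length: int = 260
    step: int = 4
    flank_extension: int = 260
    handle_5p: str = "CAGGTCATCCGGTACGATCA"  # placeholder PCR handles
    handle_3p: str = "TGACCGTCAGAGTCTGCTAC"
    max_utr_length: int = 10_000

    def __post_init__(self):
        if self.oligo_length <= 0 or self.step <= 0:
            raise DesignError("oligo_length and step must be positive")
        if self.oligo_length % self.step != 0:
            raise DesignError(
                "oligo_length must be divisible by step for uniform coverage"
            )
        for handle in (self.handle_5p, self.handle_3p):
            if handle and len(handle) != 20:
                raise DesignError("PCR handles must be exactly 20 nt when set")

    @property
    def coverage(self) -> int:
        """Number of oligos containing each interior design nucleotide."""
        return self.oligo_length // self.step


@dataclass(frozen=True)
class OligoRecord:
    """One tiled oligo; ``offset`` is relative to UTR position 0."""

    oligo_id: str
    gene_id: str
    offset: int
    insert_sequence: str
    full_sequence: str


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch ``[start, end)`` from a pyfaidx.Fasta-like or plain mapping,
    padding with N beyond chromosome bounds."""
    if end <= start:
        return ""
    source = genome[chrom]
    if hasattr(source, "__getitem__") and not isinstance(source, str):
        # pyfaidx FastaRecord supports slicing with clamping
        lo, hi = max(start, 0), max(end, 0)
        fetched = str(source[lo:hi])
    else:
        seq = str(source)
        fetched = seq[max(start, 0) : max(end, 0)]
    left_pad = max(0, -start)
    right_pad = (end - start) - left_pad - len(fetched)
    return "N" * left_pad + normalize_alphabet(fetched) + "N" * max(0, right_pad)


def merge_utrs(
    models: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    params: DesignParams | None = None,
) -> MetaUTR | None:
    """Merge the 3' UTR intervals of one gene's transcripts into a meta-UTR.

    Transcripts carrying any tag in :data:`EXCLUDED_TAGS` are dropped before
    merging. The meta-UTR spans the union of the remaining intervals projected
    onto genomic coordinates (read 5'->3' in transcript orientation) and
    carries ``flank_extension``-nt genomic flanks on both sides.

    Returns ``None`` when no transcript survives the tag filter.

    Raises
    ------
    DesignError
        If transcripts mix chromosomes or strands, or gene_ids differ.
    """
    params = params or DesignParams()
    eligible = [m for m in models if not (m.tags & EXCLUDED_TAGS)]
    if not eligible:
        if models:
            logger.info(
                "gene %s: all %d transcripts carry excluded 3'-end tags",
                models[0].gene_id,
                len(models),
            )
        return None
    gene_ids = {m.gene_id for m in eligible}
    if len(gene_ids) != 1:
        raise DesignError(f"merge_utrs received multiple gene_ids: {sorted(gene_ids)}")
    chroms = {m.chrom for m in eligible}
    strands = {m.strand for m in eligible}
    if len(chroms) != 1 or len(strands) != 1:
        raise DesignError(
            f"gene {eligible[0].gene_id}: transcripts on mixed "
            f"chromosomes/strands ({sorted(chroms)}, {sorted(strands)})"
        )
    chrom, strand = chroms.pop(), strands.pop()
    start = min(m.start for m in eligible)
    end = max(m.end for m in eligible)

    seq = _fetch(genome, chrom, start, end)
    left = _fetch(genome, chrom, start - params.flank_extension, start)
    right = _fetch(genome, chrom, end, end + params.flank_extension)
    if strand == "-":
        seq = revcomp(seq)
        upstream, downstream = revcomp(right), revcomp(left)
        polya = start
    else:
        upstream, downstream = left, right
        polya = end
    return MetaUTR(
        gene_id=eligible[0].gene_id,
        sequence=seq,
        upstream_flank=upstream,
        downstream_flank=downstream,
        source_transcripts=[m.transcript_id for m in eligible],
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        polya_site=polya,
    )


def filter_genes(
    metas: Iterable[MetaUTR],
    conserved_polya: Mapping[str, Iterable[int]] | set | None,
    params: DesignParams | None = None,
) -> tuple[list[MetaUTR], list[dict]]:
    """Apply the gene-level inclusion filters.

    Genes are retained when the meta-UTR is at most ``max_utr_length`` nt and
    the gene's polyA site lies within :data:`POLYA_CONSERVATION_WINDOW` nt of
    a conserved polyA site (inclusive). ``conserved_polya`` maps chromosome ->
    positions; a bare set of positions is accepted when chromosomes are not
    tracked (e.g. simulated data), and ``None`` disables the conservation
    filter entirely.

    Returns ``(kept, audit)`` where ``audit`` has one dict per *removed* gene
    with a ``reason`` field; nothing is silently dropped.
    """
    params = params or DesignParams()
    kept: list[MetaUTR] = []
    audit: list[dict] = []
    for meta in metas:
        if len(meta.sequence) > params.max_utr_length:
            audit.append(
                {
                    "gene_id": meta.gene_id,
                    "reason": "utr_too_long",
                    "detail": f"length={len(meta.sequence)}>{params.max_utr_length}",
                }
            )
            continue
        if conserved_polya is not None:
            if meta.polya_site is None:
                audit.append(
                    {"gene_id": meta.gene_id, "reason": "no_polya_site", "detail": ""}
                )
                continue
            if isinstance(conserved_polya, Mapping):
                sites = conserved_polya.get(meta.chrom, ())
            else:
                sites = conserved_polya
            near = any(
                abs(meta.polya_site - s) <= POLYA_CONSERVATION_WINDOW for s in sites
            )
            if not near:
                audit.append(
                    {
                        "gene_id": meta.gene_id,
                        "reason": "polya_not_conserved",
                        "detail": f"polya={meta.polya_site}",
                    }
                )
                continue
        kept.append(meta)
    for row in audit:
        logger.info("gene %(gene_id)s filtered: %(reason)s %(detail)s", row)
    return kept, audit


def tile_oligos(meta: MetaUTR, params: DesignParams | None = None) -> list[OligoRecord]:
    """Tile one meta-UTR into oligos.

    The design sequence is ``upstream_flank + UTR + downstream_flank``; flanks
    shorter than ``flank_extension`` are N-padded (and logged). Oligo starts
    run from 0 to ``len(design) - oligo_length`` in ``step`` increments; when
    the remainder is nonzero a final oligo is anchored flush with the 3' end
    so the last nucleotides are always covered.
    """
    params = params or DesignParams()
    up, down = meta.upstream_flank, meta.downstream_flank
    if len(up) < params.flank_extension:
        logger.warning(
            "gene %s: upstream flank %d < %d nt, N-padding",
            meta.gene_id,
            len(up),
            params.flank_extension,
        )
        up = "N" * (params.flank_extension - len(up)) + up
    if len(down) < params.flank_extension:
        logger.warning(
            "gene %s: downstream flank %d < %d nt, N-padding",
            meta.gene_id,
            len(down),
            params.flank_extension,
        )
        down = down + "N" * (params.flank_extension - len(down))
    design = up + meta.sequence + down
    L, olen = len(design), params.oligo_length
    if L < olen:
        raise DesignError(
            f"gene {meta.gene_id}: design sequence {L} nt shorter than oligo "
            f"length {olen}"
        )
    starts = list(range(0, L - olen + 1, params.step))
    if starts[-1] != L - olen:
        starts.append(L - olen)  # anchored final oligo: full 3'-end coverage
    pad = max(4, len(str(len(starts))))
    records = []
    for i, s in enumerate(starts):
        insert = design[s : s + olen]
        records.append(
            OligoRecord(
                oligo_id=f"{meta.gene_id}|{i:0{pad}d}",
                gene_id=meta.gene_id,
                offset=s - params.flank_extension,
                insert_sequence=insert,
                full_sequence=params.handle_5p + insert + params.handle_3p,
            )
        )
    return records


def add_controls(
    pool: list[OligoRecord],
    control_seqs: Sequence[tuple[str, str]],
    params: DesignParams | None = None,
    mode: str = "whole",
    n_placements: int = 3,
) -> list[OligoRecord]:
    """Append control oligos to a pool under the ``ctrl:`` gene namespace.

    ``mode='whole'`` embeds each control sequence (<= oligo_length nt) whole
    at ``n_placements`` evenly spaced positions within an oligo-length window;
    padding is deterministic pseudo-random sequence derived from the control
    name, so output is reproducible. ``mode='tile'`` tiles each control like a
    UTR (no flank extension).
    """
    params = params or DesignParams()
    out = list(pool)
    seen = {r.oligo_id for r in pool}
    for name, raw_seq in control_seqs:
        seq = normalize_alphabet(raw_seq)
        gene_id = f"ctrl:{name}"
        if mode == "tile":
            meta = MetaUTR(gene_id=gene_id, sequence=seq, upstream_flank="", downstream_flank="")
            tiled = tile_oligos(
                meta,
                DesignParams(
                    oligo_length=params.oligo_length,
                    step=params.step,
                    flank_extension=0,
                    handle_5p=params.handle_5p,
                    handle_3p=params.handle_3p,
                    max_utr_length=params.max_utr_length,
                ),
            )
            new = tiled
        elif mode == "whole":
            if len(seq) > params.oligo_length:
                raise DesignError(
                    f"control {name}: {len(seq)} nt exceeds oligo length in whole mode"
                )
            slack = params.oligo_length - len(seq)
            if n_placements == 1:
                positions = [slack // 2]
            else:
                positions = [
                    round(i * slack / (n_placements - 1)) for i in range(n_placements)
                ]
            rng = np.random.default_rng(
                np.frombuffer(name.encode() + b"\x00pad", dtype=np.uint8).sum() + 1
            )
            pad_pool = "".join(rng.choice(list("ACGT"), size=params.oligo_length * 2))
            new = []
            for i, pos in enumerate(positions):
                insert = pad_pool[:pos] + seq + pad_pool[pos : slack]
                assert len(insert) == params.oligo_length
                new.append(
                    OligoRecord(
                        oligo_id=f"{gene_id}|{i:04d}",
                        gene_id=gene_id,
                        offset=pos,
                        insert_sequence=insert,
                        full_sequence=params.handle_5p + insert + params.handle_3p,
                    )
                )
        else:
            raise DesignError(f"unknown control mode {mode!r}")
        for rec in new:
            if rec.oligo_id in seen:
                raise DesignError(f"duplicate oligo_id {rec.oligo_id}")
            seen.add(rec.oligo_id)
        out.extend(new)
    return out


# ---------------------------------------------------------------------------
# Annotation input and pool output
# ---------------------------------------------------------------------------


def read_transcript_models(gtf_path: str | Path) -> list[TranscriptModel]:
    """Read 3' UTR intervals from a GTF/GFF file.

    Uses ``three_prime_utr`` (or ``three_prime_UTR``) features; multiple UTR
    features of one transcript are collapsed to their genomic span. Repeated
    ``tag`` attributes are all collected.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, dict] = {}
    for ftype in ("three_prime_utr", "three_prime_UTR"):
        for feat in db.features_of_type(ftype):
            tx = feat.attributes.get("transcript_id", [feat.id])[0]
            gene = feat.attributes.get("gene_id", [tx])[0]
            tags = frozenset(feat.attributes.get("tag", []))
            entry = per_tx.setdefault(
                tx,
                {
                    "gene": gene,
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "start": feat.start - 1,  # gffutils is 1-based inclusive
                    "end": feat.end,
                    "tags": tags,
                },
            )
            entry["start"] = min(entry["start"], feat.start - 1)
            entry["end"] = max(entry["end"], feat.end)
            entry["tags"] = entry["tags"] | tags
    return [
        TranscriptModel(
            transcript_id=tx,
            gene_id=e["gene"],
            chrom=e["chrom"],
            start=e["start"],
            end=e["end"],
            strand=e["strand"],
            tags=e["tags"],
        )
        for tx, e in per_tx.items()
    ]


def read_polya_bed(bed_path: str | Path) -> dict[str, list[int]]:
    """Read conserved polyA sites from a BED file (chromStart used as site)."""
    sites: dict[str, list[int]] = {}
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            sites.setdefault(fields[0], []).append(int(fields[1]))
    return sites


def write_pool(
    pool: Sequence[OligoRecord], out_prefix: str | Path
) -> tuple[Path, Path]:
    """Write the pool FASTA (full sequences) and manifest TSV.

    Output is deterministic: records are emitted in pool order with fixed
    formatting, so identical inputs give byte-identical files.
    """
    out_prefix = Path(out_prefix)
    fasta = out_prefix.with_suffix(".fasta")
    manifest = out_prefix.with_suffix(".manifest.tsv")
    write_fasta(
        fasta,
        (
            (r.oligo_id, f"gene={r.gene_id} offset={r.offset}", r.full_sequence)
            for r in pool
        ),
    )
    with open(manifest, "w") as fh:
        fh.write("oligo_id\tgene_id\toffset\tinsert_sequence\n")
        for r in pool:
            fh.write(f"{r.oligo_id}\t{r.gene_id}\t{r.offset}\t{r.insert_sequence}\n")
    return fasta, manifest


def read_manifest(path: str | Path) -> list[OligoRecord]:
    """Read a pool manifest TSV back into records (handles left empty)."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            insert = f[idx["insert_sequence"]]
            records.append(
                OligoRecord(
                    oligo_id=f[idx["oligo_id"]],
                    gene_id=f[idx["gene_id"]],
                    offset=int(f[idx["offset"]]),
                    insert_sequence=insert,
                    full_sequence=insert,
                )
            )
    return records
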