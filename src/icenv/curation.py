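"""Curation of domain hits: envelope extraction, length and e-value filters.

Gene models annotated with a profile-HMM domain (here the ice-binding-like
family PF11999) arrive as a per-domain tabular report ("domtblout"). Curation
keeps the envelope region of each hit, discards short or weak hits, and gives
multi-domain genes unique per-domain identifiers.

Thresholds follow the study defaults: hits shorter than 150 residues or with
an independent domain e-value above 1e-10 are removed; equality at either
boundary passes. The length unit is residues by default (``unit='aa'``); a
``unit='bp'`` mode divides the threshold by three for nucleotide-scale
thresholds applied to translated models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from .seqs import SequenceRecord, SequenceSet

DEFAULT_MIN_LENGTH = 150
DEFAULT_MAX_EVALUE = 1e-10


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM domain hit with its envelope coordinates (1-based)."""

    gene_id: str
    family: str
    envelope_start: int
    envelope_end: int
    domain_evalue: float

    def __post_init__(self) -> None:
        if not 1 <= self.envelope_start <= self.envelope_end:
            raise ValueError(
                f"hit on {self.gene_id!r}: invalid envelope "
                f"{self.envelope_start}..{self.envelope_end}"
            )
        if self.domain_evalue <= 0:
            raise ValueError(f"hit on {self.gene_id!r}: e-value must be > 0")

    @property
    def length(self) -> int:
        return self.envelope_end - self.envelope_start + 1


# domtblout whitespace-separated field indices (0-based)
_F_TARGET = 0
_F_QUERY_ACC = 4
_F_IEVALUE = 12
_F_ENV_FROM = 19
_F_ENV_TO = 20
_MIN_FIELDS = 22


def parse_domain_hits(stream: IO[str] | Iterable[str]) -> list[DomainHit]:
    """Parse hmmer per-domain tabular output into :class:`DomainHit` rows.

    Envelope coordinates come from the ``env from``/``env to`` columns and
    the independent e-value (i-Evalue) is used as the domain e-value.
    """
    hits: list[DomainHit] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < _MIN_FIELDS:
            raise ValueError(
                f"domtblout line {lineno}: expected >= {_MIN_FIELDS} fields, "
                f"got {len(fields)}"
            )
        try:
            hit = DomainHit(
                gene_id=fields[_F_TARGET],
                family=fields[_F_QUERY_ACC],
                envelope_start=int(fields[_F_ENV_FROM]),
                envelope_end=int(fields[_F_ENV_TO]),
                domain_evalue=float(fields[_F_IEVALUE]),
            )
        except ValueError as exc:
            raise ValueError(f"domtblout line {lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def filter_hits(
    hits: Iterable[DomainHit],
    min_length: int = DEFAULT_MIN_LENGTH,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    unit: str = "aa",
) -> list[DomainHit]:
    """Keep hits with envelope length >= min_length and e-value <= max_evalue.

    The removal rules are strict inequalities (shorter than the threshold,
    larger than the e-value), so boundary values are retained. Order is
    preserved and the filter is idempotent.
    """
    if min_length <= 0 or max_evalue <= 0:
        raise ValueError("thresholds must be positive")
    if unit not in ("aa", "bp"):
        raise ValueError(f"unknown length unit {unit!r}")
    effective = min_length if unit == "aa" else min_length / 3
    return [
        h for h in hits if h.length >= effective and h.domain_evalue <= max_evalue
    ]


def extract_envelopes(
    genes: SequenceSet, hits: Iterable[DomainHit]
) -> SequenceSet:
    """Cut each hit's envelope out of its gene; rename multi-domain genes.

    Genes with a single hit keep their id; genes with k > 1 hits yield
    ``<gene_id>_1`` .. ``<gene_id>_k`` in hit order, so every extracted
    domain has a unique label.
    """
    hits = list(hits)
    by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    gene_index = {r.id: r for r in genes}

    records: list[SequenceRecord] = []
    for gene_id, gene_hits in by_gene.items():
        if gene_id not in gene_index:
            raise KeyError(f"hit references unknown gene {gene_id!r}")
        gene = gene_index[gene_id]
        for k, h in enumerate(gene_hits, start=1):
            if h.envelope_end > len(gene.residues):
                raise ValueError(
                    f"hit on {gene_id!r}: envelope end {h.envelope_end} exceeds "
                    f"gene length {len(gene.residues)}"
                )
            out_id = gene_id if len(gene_hits) == 1 else f"{gene_id}_{k}"
            records.append(
                SequenceRecord(
                    id=out_id,
                    residues=gene.residues[h.envelope_start - 1 : h.envelope_end],
                    environment=gene.environment,
                    phylum=gene.phylum,
                )
            )
    return SequenceSet(records)


def curate(
    genes: SequenceSet,
    hits: Iterable[DomainHit],
    min_length: int = DEFAULT_MIN_LENGTH,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    unit: str = "aa",
) -> SequenceSet:
    """Composed curation: filter hits, then extract their envelopes."""
    return extract_envelopes(
        genes, filter_hits(hits, min_length=min_length, max_evalue=max_evalue, unit=unit)
    )
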