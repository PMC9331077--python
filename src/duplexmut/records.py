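"""Sample metadata, duplex depth tables, and somatic mutation call records.

The package starts downstream of consensus calling: its inputs are per-sample
variant calls (VCF or the documented TSV dialect below), a duplex-depth table
giving the number of duplex base pairs sequenced per (sample, target), and a
sample sheet with dose assignments.

TSV mutation dialect (tab-separated, header required)::

    sample_id  target  chrom  pos  ref  alt  multiplicity  tri_context

``pos`` is 1-based; ``multiplicity`` is the number of duplex molecules
carrying the call (>= 1, clonal expansions appear as multiplicity > 1);
``tri_context`` is the central-pyrimidine trinucleotide context and may be
empty for non-SNV calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import pyrimidine_channel
from .panel import PanelTarget

logger = logging.getLogger(__name__)

VAR_CLASSES = ("SNV", "insertion", "deletion", "MNV")


def classify_variant(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) < len(alt):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    return "MNV"


@dataclass
class MutationRecord:
    """One called somatic variant in one sample."""

    sample_id: str
    target: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    multiplicity: int = 1
    tri_context: str | None = None

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref equals alt")

    @property
    def var_class(self) -> str:
        return classify_variant(self.ref, self.alt)

    @property
    def key(self) -> tuple:
        """Identity of the mutation within its sample (for deduplication)."""
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)

    def channel(self) -> str | None:
        """96-channel label, or None for non-SNVs / missing context."""
        if self.var_class != "SNV" or not self.tri_context:
            return None
        ref, alt = self.ref, self.alt
        ctx = self.tri_context
        if ctx[1] != ref:
            # context stored pyrimidine-normalized while ref is purine strand
            from .channels import COMPLEMENT, revcomp

            ref, alt, _ = COMPLEMENT[ref], COMPLEMENT[alt], None
            if ctx[1] != ref:
                raise ValueError(
                    f"{self.chrom}:{self.pos}: context {ctx!r} inconsistent with ref"
                )
        return pyrimidine_channel(ref, alt, ctx)


@dataclass
class SampleMeta:
    sample_id: str
    dose: float
    group: str = ""

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"sample {self.sample_id}: negative dose")
        if not self.group:
            self.group = f"{self.dose:g}"


class DepthTable:
    """Duplex base pairs sequenced per (sample, target)."""

    def __init__(self, entries: dict[tuple[str, str], int]):
        if any(v < 0 for v in entries.values()):
            raise ValueError("duplex_bp must be nonnegative")
        self._s = pd.Series(entries, dtype="int64")
        self._s.index = pd.MultiIndex.from_tuples(self._s.index, names=["sample_id", "target"])

    def get(self, sample_id: str, target: str) -> int:
        return int(self._s[(sample_id, target)])

    def sample_total(self, sample_id: str) -> int:
        return int(self._s.xs(sample_id, level="sample_id").sum())

    def total(self) -> int:
        return int(self._s.sum())

    def to_frame(self) -> pd.DataFrame:
        return self._s.rename("duplex_bp").reset_index()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DepthTable":
        return cls(
            {
                (r.sample_id, r.target): int(r.duplex_bp)
                for r in df.itertuples(index=False)
            }
        )

    def validate_grid(self, samples: list[str], targets: list[str]) -> None:
        missing = [
            (s, t) for s in samples for t in targets if (s, t) not in self._s.index
        ]
        if missing:
            raise ValueError(f"depth table missing {len(missing)} (sample, target) cells")

    def __eq__(self, other) -> bool:
        return isinstance(other, DepthTable) and self._s.sort_index().equals(
            other._s.sort_index()
        )


# ---- assignment to panel targets ------------------------------------------


def assign_target(chrom: str, pos: int, ref: str, panel: list[PanelTarget]) -> PanelTarget | None:
    """The unique panel target containing a (possibly multi-base) call."""
    end = pos + max(len(ref) - 1, 0)
    hits = [t for t in panel if t.chrom == chrom and t.contains(pos)]
    if not hits:
        known = {t.chrom for t in panel}
        if chrom not in known:
            raise ValueError(f"unknown chromosome {chrom!r}")
        return None
    target = hits[0]
    if not target.contains(end):
        raise ValueError(f"call at {chrom}:{pos} spans the target boundary of {target.name}")
    return target


# ---- TSV I/O ---------------------------------------------------------------

MUTATION_COLUMNS = [
    "sample_id",
    "target",
    "chrom",
    "pos",
    "ref",
    "alt",
    "multiplicity",
    "tri_context",
]


def mutations_to_frame(mutations: list[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (m.sample_id, m.target, m.chrom, m.pos, m.ref, m.alt, m.multiplicity, m.tri_context or "")
            for m in mutations
        ],
        columns=MUTATION_COLUMNS,
    )


def frame_to_mutations(df: pd.DataFrame) -> list[MutationRecord]:
    ctx = df["tri_context"].fillna("") if "tri_context" in df else [""] * len(df)
    return [
        MutationRecord(
            sample_id=str(r.sample_id),
            target=str(r.target),
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            multiplicity=int(getattr(r, "multiplicity", 1)),
            tri_context=str(c) or None,
        )
        for r, c in zip(df.itertuples(index=False), ctx)
    ]


def write_mutations_tsv(mutations: list[MutationRecord], path) -> None:
    mutations_to_frame(mutations).to_csv(path, sep="\t", index=False)


def read_mutations_tsv(path, panel: list[PanelTarget] | None = None) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"tri_context": "string"})
    records = frame_to_mutations(df)
    if panel is not None:
        records = _assign_and_filter(records, panel)
    return records


def _assign_and_filter(records: list[MutationRecord], panel: list[PanelTarget]) -> list[MutationRecord]:
    kept, dropped = [], 0
    for rec in records:
        target = assign_target(rec.chrom, rec.pos, rec.ref, panel)
        if target is None:
            dropped += 1
            continue
        rec.target = target.name
        kept.append(rec)
    if dropped:
        logger.warning("dropped %d calls outside all panel targets", dropped)
    return kept


def read_mutations(path, panel: list[PanelTarget]) -> list[MutationRecord]:
    """Read mutation calls from VCF (``.vcf``) or the TSV dialect.

    Every call is assigned to the unique containing target; calls outside all
    targets are dropped (count logged).  VCF multiplicity is taken from the
    ``AD`` (alt duplex molecule count) INFO field when present, else 1.
    """
    path = str(path)
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        return _read_vcf(path, panel)
    return read_mutations_tsv(path, panel)


def _read_vcf(path: str, panel: list[PanelTarget]) -> list[MutationRecord]:
    import pysam

    records = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            sample_id = rec.info.get("SAMPLE")
            if sample_id is None and rec.samples:
                sample_id = next(iter(rec.samples))
            mult = rec.info.get("AD", 1)
            if isinstance(mult, tuple):
                mult = mult[0]
            ctx = rec.info.get("TRI")
            for alt in rec.alts or ():
                records.append(
                    MutationRecord(
                        sample_id=str(sample_id),
                        target="",
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        multiplicity=int(mult),
                        tri_context=str(ctx) if ctx else None,
                    )
                )
    return _assign_and_filter(records, panel)


def write_mutations_vcf(mutations: list[MutationRecord], panel: list[PanelTarget], path) -> None:
    """Write calls as a minimal VCF v4.2 with per-call INFO annotations."""
    import pysam

    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(t.chrom for t in panel):
        end = max(t.end for t in panel if t.chrom == chrom)
        header.contigs.add(chrom, length=end + 1000)
    header.info.add("SAMPLE", 1, "String", "Sample identifier")
    header.info.add("TARGET", 1, "String", "Panel target name")
    header.info.add("AD", 1, "Integer", "Duplex molecules carrying the variant")
    header.info.add("TRI", 1, "String", "Central-pyrimidine trinucleotide context")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for m in sorted(mutations, key=lambda m: (m.chrom, m.pos, m.sample_id)):
            rec = out.new_record(
                contig=m.chrom, start=m.pos - 1, alleles=(m.ref, m.alt)
            )
            rec.info["SAMPLE"] = m.sample_id
            rec.info["TARGET"] = m.target
            rec.info["AD"] = m.multiplicity
            if m.tri_context:
                rec.info["TRI"] = m.tri_context
            out.write(rec)


def write_depths_tsv(depths: DepthTable, path) -> None:
    depths.to_frame().to_csv(path, sep="\t", index=False)


def read_depths_tsv(path) -> DepthTable:
    return DepthTable.from_frame(pd.read_csv(path, sep="\t"))


def write_metadata_tsv(metadata: list[SampleMeta], path) -> None:
    pd.DataFrame(
        [(m.sample_id, m.dose, m.group) for m in metadata],
        columns=["sample_id", "dose", "group"],
    ).to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    metas = [
        SampleMeta(
            str(r.sample_id),
            float(r.dose),
            "" if pd.isna(g := getattr(r, "group", "")) else str(g),
        )
        for r in df.itertuples(index=False)
    ]
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in metadata")
    return metas
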