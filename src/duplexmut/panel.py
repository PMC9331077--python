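"""Mutagenesis panel model: genomic target intervals and their annotations.

A panel is a small set of capture targets (the default emulates a rodent
mutagenesis panel of twenty ~2.4 kb intervals spread over the autosomes,
9 genic and 11 intergenic, seven in inferred heterochromatin).  Each target
carries the annotations the downstream stratified analyses need: genic vs
intergenic status, chromatin state, GC fraction, an optional expression
level, and — when a reference sequence is attached — the trinucleotide
abundance vector used for context-normalized spectra and for placing
simulated mutations at real context-matching sites.

Coordinates follow the BED convention on disk (0-based, half-open); mutation
positions elsewhere in the package are 1-based (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import COMPLEMENT, PYR_CONTEXTS_32, PYRIMIDINES, revcomp

REGION_CLASSES = ("genic", "intergenic")
CHROMATIN_STATES = ("euchromatin", "heterochromatin")


@dataclass
class PanelTarget:
    """One panel interval with its genomic-feature annotations."""

    name: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    region_class: str = "intergenic"
    chromatin: str = "euchromatin"
    gc_fraction: float = float("nan")
    expression_level: float | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"target {self.name}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"target {self.name}: bad region_class {self.region_class!r}")
        if self.chromatin not in CHROMATIN_STATES:
            raise ValueError(f"target {self.name}: bad chromatin {self.chromatin!r}")
        if not np.isnan(self.gc_fraction) and not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"target {self.name}: gc_fraction outside [0,1]")
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"target {self.name}: sequence length {len(self.sequence)} != "
                    f"interval length {self.length}"
                )
            if np.isnan(self.gc_fraction):
                gc = sum(b in "GC" for b in self.sequence)
                self.gc_fraction = gc / self.length

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos_1based: int) -> bool:
        """Whether a 1-based position lies inside the interval."""
        return self.start < pos_1based <= self.end

    # ---- sequence-derived annotations -------------------------------------

    def tri_abundance(self) -> np.ndarray:
        """Counts of the 32 central-pyrimidine trinucleotides in the target.

        Each interior position contributes once: purine-centred trinucleotides
        are folded to the reverse-complement strand, so the vector sums to the
        number of interior positions (length − 2).
        """
        if self.sequence is None:
            raise ValueError(f"target {self.name} has no attached sequence")
        counts = dict.fromkeys(PYR_CONTEXTS_32, 0)
        seq = self.sequence
        for i in range(1, len(seq) - 1):
            tri = seq[i - 1 : i + 2]
            if tri[1] not in PYRIMIDINES:
                tri = revcomp(tri)
            counts[tri] += 1
        return np.array([counts[c] for c in PYR_CONTEXTS_32], dtype=int)

    def context_positions(self) -> dict[str, np.ndarray]:
        """Map each pyrimidine context to the 1-based positions showing it."""
        if self.sequence is None:
            raise ValueError(f"target {self.name} has no attached sequence")
        index: dict[str, list[int]] = {c: [] for c in PYR_CONTEXTS_32}
        seq = self.sequence
        for i in range(1, len(seq) - 1):
            tri = seq[i - 1 : i + 2]
            if tri[1] not in PYRIMIDINES:
                tri = revcomp(tri)
            index[tri].append(self.start + i + 1)  # 1-based genomic
        return {c: np.array(p, dtype=int) for c, p in index.items()}

    def cpg_sites(self) -> np.ndarray:
        """1-based positions of the C of each CpG dinucleotide (one per CpG)."""
        if self.sequence is None:
            raise ValueError(f"target {self.name} has no attached sequence")
        seq = self.sequence
        return np.array(
            [self.start + i + 1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"],
            dtype=int,
        )

    def base_at(self, pos_1based: int) -> str:
        if self.sequence is None:
            raise ValueError(f"target {self.name} has no attached sequence")
        return self.sequence[pos_1based - 1 - self.start]


def validate_panel(targets: list[PanelTarget]) -> list[PanelTarget]:
    """Sort targets by (chrom, start) and reject duplicates/overlaps."""
    names = [t.name for t in targets]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate target names: {sorted(dupes)}")
    out = sorted(targets, key=lambda t: (t.chrom, t.start))
    for a, b in zip(out, out[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"targets {a.name} and {b.name} overlap on {a.chrom}")
    return out


def read_panel(path) -> list[PanelTarget]:
    """Read a panel from a BED-like file.

    Columns: chrom, start, end, name, then optionally region_class,
    chromatin, gc_fraction, expression_level.  Coordinates are 0-based
    half-open.  Lines starting with ``#`` or ``track`` are skipped.
    """
    targets: list[PanelTarget] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 columns, got {len(parts)}")
            chrom, start_s, end_s, name = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            kwargs = {}
            if len(parts) > 4 and parts[4]:
                kwargs["region_class"] = parts[4]
            if len(parts) > 5 and parts[5]:
                kwargs["chromatin"] = parts[5]
            if len(parts) > 6 and parts[6]:
                kwargs["gc_fraction"] = float(parts[6])
            if len(parts) > 7 and parts[7] not in ("", "NA", "."):
                kwargs["expression_level"] = float(parts[7])
            try:
                targets.append(PanelTarget(name, chrom, start, end, **kwargs))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return validate_panel(targets)


def write_panel(targets: list[PanelTarget], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tregion_class\tchromatin\tgc_fraction\texpression\n")
        for t in targets:
            expr = "" if t.expression_level is None else f"{t.expression_level:g}"
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.name}\t{t.region_class}\t"
                f"{t.chromatin}\t{t.gc_fraction:.4f}\t{expr}\n"
            )


# ---- default panel ---------------------------------------------------------

# Fixed layout of the default 20-target panel: (name, chrom, region_class,
# chromatin, target GC fraction).  Two targets sit on chromosome 1; 9 targets
# are genic and 11 intergenic; 7 fall in inferred heterochromatin.  GC
# fractions span a narrow band (~0.36-0.50, mean ~0.429), mirroring a
# balanced capture design.
_DEFAULT_LAYOUT = [
    ("chr1.1", "chr1", "intergenic", "euchromatin", 0.390),
    ("chr1.2", "chr1", "intergenic", "euchromatin", 0.410),
    ("chr2", "chr2", "intergenic", "heterochromatin", 0.420),
    ("chr3", "chr3", "genic", "euchromatin", 0.455),
    ("chr4", "chr4", "intergenic", "euchromatin", 0.400),
    ("chr5", "chr5", "genic", "euchromatin", 0.470),
    ("chr6", "chr6", "intergenic", "euchromatin", 0.385),
    ("chr7", "chr7", "genic", "euchromatin", 0.480),
    ("chr8", "chr8", "intergenic", "euchromatin", 0.405),
    ("chr9", "chr9", "genic", "euchromatin", 0.460),
    ("chr10", "chr10", "intergenic", "euchromatin", 0.395),
    ("chr11", "chr11", "intergenic", "heterochromatin", 0.430),
    ("chr12", "chr12", "genic", "euchromatin", 0.445),
    ("chr13", "chr13", "genic", "heterochromatin", 0.435),
    ("chr14", "chr14", "intergenic", "heterochromatin", 0.415),
    ("chr15", "chr15", "genic", "heterochromatin", 0.465),
    ("chr16", "chr16", "intergenic", "heterochromatin", 0.425),
    ("chr17", "chr17", "intergenic", "euchromatin", 0.440),
    ("chr18", "chr18", "genic", "heterochromatin", 0.360),
    ("chr19", "chr19", "genic", "euchromatin", 0.495),
]

_PANEL_SEQ_SEED = 202207  # fixed: the default panel is a constant, not a random draw
TARGET_LENGTH = 2400


def default_panel(target_length: int = TARGET_LENGTH) -> list[PanelTarget]:
    """Construct the default 20-target panel with attached synthetic sequences.

    Sequences are drawn once from a fixed generator so the default panel is
    identical across processes; per-target GC content follows the layout
    above.  Expression levels (RPKM-like) are attached to genic targets only.
    """
    rng = np.random.default_rng(_PANEL_SEQ_SEED)
    targets = []
    next_start: dict[str, int] = {}
    for name, chrom, region, chromatin, gc in _DEFAULT_LAYOUT:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = "".join(rng.choice(list("ACGT"), size=target_length, p=p))
        expr = round(float(rng.gamma(2.0, 8.0)), 2) if region == "genic" else None
        start = next_start.get(chrom, 1_000_000)  # arbitrary but fixed anchors
        next_start[chrom] = start + 10_000_000
        targets.append(
            PanelTarget(
                name=name,
                chrom=chrom,
                start=start,
                end=start + target_length,
                region_class=region,
                chromatin=chromatin,
                expression_level=expr,
                sequence=seq,
            )
        )
    return validate_panel(targets)
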