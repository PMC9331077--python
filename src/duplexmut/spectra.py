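"""Substitution spectra: 6-class and 96-channel trinucleotide summaries.

Spectra are built from deduplicated calls.  Indels and MNVs are excluded
from the 96-channel spectrum (consistent with SBS-signature methodology) and
tallied separately in the 6-class summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .channels import CHANNELS_96, CHANNEL_INDEX, PYR_CONTEXTS_32, SUB_CLASSES, channel_parts, channel_sub_class
from .mf import holm_sidak
from .panel import PanelTarget
from .records import MutationRecord

logger = logging.getLogger(__name__)

NORMALIZATIONS = ("counts", "per_bp", "per_context_bp", "proportion")


@dataclass
class Spectrum6:
    """6-class SNV spectrum plus indel/MNV tallies."""

    counts: pd.Series  # indexed by SUB_CLASSES
    insertions: int = 0
    deletions: int = 0
    mnvs: int = 0

    @property
    def proportions(self) -> pd.Series:
        total = self.counts.sum()
        if total == 0:
            return self.counts * 0.0
        return self.counts / total

    def sub_share(self, sub_class: str) -> float:
        """Share of SNVs in one substitution class (e.g. C>A for C:G>A:T)."""
        return float(self.proportions[sub_class])


@dataclass
class Spectrum96:
    """96-channel spectrum under a declared normalization."""

    values: pd.Series  # indexed by CHANNELS_96
    normalization: str = "counts"
    label: str = ""

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        self.values = self.values.reindex(list(CHANNELS_96)).fillna(0.0)

    def as_proportions(self) -> "Spectrum96":
        total = self.values.sum()
        if total <= 0:
            raise ValueError("cannot normalize an empty spectrum")
        return Spectrum96(self.values / total, "proportion", self.label)

    def to_spectrum6(self) -> Spectrum6:
        by_class = self.values.groupby(
            self.values.index.map(channel_sub_class)
        ).sum().reindex(list(SUB_CLASSES), fill_value=0.0)
        return Spectrum6(counts=by_class)


def build_spectrum(
    mutations: list[MutationRecord],
    normalization: str = "counts",
    duplex_bp: int | None = None,
    tri_abundance: np.ndarray | None = None,
    label: str = "",
) -> tuple[Spectrum96, Spectrum6]:
    """Tally deduplicated calls into a 96-channel and a 6-class spectrum.

    ``per_bp`` divides channel counts by ``duplex_bp``; ``per_context_bp``
    divides each channel by (count of its trinucleotide context in the panel
    x duplex depth), i.e. opportunity-normalized frequencies, and requires
    ``tri_abundance`` (32-vector in the order of :data:`PYR_CONTEXTS_32`)
    plus ``duplex_bp``.
    """
    counts = np.zeros(96)
    ins = dele = mnv = 0
    for m in mutations:
        vc = m.var_class
        if vc == "SNV":
            ch = m.channel()
            if ch is None:
                logger.warning("SNV at %s:%d lacks context; skipped", m.chrom, m.pos)
                continue
            counts[CHANNEL_INDEX[ch]] += 1
        elif vc == "insertion":
            ins += 1
        elif vc == "deletion":
            dele += 1
        else:
            mnv += 1
    raw = pd.Series(counts, index=list(CHANNELS_96))
    six = Spectrum6(
        counts=raw.groupby(raw.index.map(channel_sub_class)).sum().reindex(list(SUB_CLASSES)),
        insertions=ins,
        deletions=dele,
        mnvs=mnv,
    )
    if normalization == "counts":
        values = raw
    elif normalization == "proportion":
        total = raw.sum()
        values = raw / total if total > 0 else raw
    elif normalization == "per_bp":
        if not duplex_bp:
            raise ValueError("per_bp normalization requires duplex_bp")
        values = raw / duplex_bp
    elif normalization == "per_context_bp":
        if tri_abundance is None:
            raise ValueError("per_context_bp normalization requires tri_abundance")
        if not duplex_bp:
            raise ValueError("per_context_bp normalization requires duplex_bp")
        abundance = dict(zip(PYR_CONTEXTS_32, np.asarray(tri_abundance, dtype=float)))
        denom = np.array([abundance[channel_parts(ch)[0]] for ch in CHANNELS_96])
        if (denom == 0).any():
            logger.warning("%d contexts absent from the panel", int((denom == 0).sum()))
        mean_site_depth = duplex_bp / max(sum(abundance.values()), 1)
        values = raw / np.where(denom > 0, denom * mean_site_depth, np.nan)
    else:  # pragma: no cover
        raise ValueError(normalization)
    return Spectrum96(values, normalization, label), six


def spectra_by_group(
    mutations: list[MutationRecord],
    group_of: dict[str, str],
    normalization: str = "counts",
) -> dict[str, tuple[Spectrum96, Spectrum6]]:
    """Build one pooled spectrum per group (``group_of`` maps sample -> group)."""
    buckets: dict[str, list[MutationRecord]] = {}
    for m in mutations:
        buckets.setdefault(group_of[m.sample_id], []).append(m)
    return {
        g: build_spectrum(ms, normalization=normalization, label=g)
        for g, ms in sorted(buckets.items())
    }


# ---- spectrum homogeneity testing ------------------------------------------


def spectrum_contingency_test(
    tables: pd.DataFrame,
    control_group: str | None = None,
    n_mc: int = 9999,
    seed: int = 0,
) -> dict:
    """Monte Carlo homogeneity test of mutation-class spectra across groups.

    ``tables`` is a groups x classes count table (rows are groups).  The
    overall statistic is the Pearson chi-square; its p-value is estimated by
    Monte Carlo with row totals fixed (each group's class vector resampled
    from the pooled class proportions), which stays valid for the sparse
    tables typical of mutation-class data.  Per-class follow-ups compare each
    class against the rest between each group and the control group (2x2
    chi-square), Holm-Sidak adjusted across classes within each group pair.

    Returns a dict with ``statistic``, ``p_value``, and ``per_class`` (a
    DataFrame of follow-up contrasts).
    """
    tab = tables.copy()
    if (tab.sum(axis=1) == 0).any():
        empty = tab.index[tab.sum(axis=1) == 0].tolist()
        raise ValueError(f"groups with zero total mutations: {empty}")
    dead = tab.columns[tab.sum(axis=0) == 0]
    if len(dead):
        logger.warning("dropping all-zero classes: %s", list(dead))
        tab = tab.drop(columns=dead)
    observed = tab.to_numpy(dtype=float)
    stat = _pearson_chi2(observed)
    rng = np.random.default_rng(seed)
    pooled = observed.sum(axis=0)
    p_class = pooled / pooled.sum()
    row_totals = observed.sum(axis=1).astype(int)
    exceed = 0
    for _ in range(n_mc):
        sim = np.vstack([rng.multinomial(n, p_class) for n in row_totals])
        if _pearson_chi2(sim) >= stat - 1e-12:
            exceed += 1
    p_value = (1 + exceed) / (n_mc + 1)

    control = control_group if control_group is not None else tab.index[0]
    rows = []
    for group in tab.index:
        if group == control:
            continue
        raw_ps, stats_ = [], []
        for cls in tab.columns:
            a = np.array(
                [
                    [tab.loc[group, cls], tab.loc[group].sum() - tab.loc[group, cls]],
                    [tab.loc[control, cls], tab.loc[control].sum() - tab.loc[control, cls]],
                ],
                dtype=float,
            )
            if a[:, 0].sum() == 0 or a[:, 1].sum() == 0:
                raw_ps.append(1.0)
                stats_.append(0.0)
                continue
            c2, p, _, _ = chi2_contingency(a, correction=False)
            raw_ps.append(float(p))
            stats_.append(float(c2))
        adj = holm_sidak(raw_ps)
        for cls, s, p, pa in zip(tab.columns, stats_, raw_ps, adj):
            rows.append((group, control, cls, s, p, float(pa)))
    per_class = pd.DataFrame(
        rows, columns=["group", "control", "class", "chi2", "p_raw", "p_adjusted"]
    )
    return {"statistic": stat, "p_value": p_value, "per_class": per_class}


def _pearson_chi2(table: np.ndarray) -> float:
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


# ---- CpG site analysis -----------------------------------------------------


def cpg_mutated_fraction(
    mutations: list[MutationRecord],
    panel: list[PanelTarget],
) -> float:
    """Fraction of panel CpG dinucleotide sites carrying >=1 mutation.

    A CpG site is one dinucleotide (counted once, not per strand); a mutation
    hits it if it falls on either the C or the G of the pair.  Requires
    targets with attached sequences (the CpG inventory).
    """
    cpg_by_target = {}
    for t in panel:
        if t.sequence is None:
            raise ValueError(f"target {t.name} has no sequence: CpG inventory missing")
        cpg_by_target[t.name] = set(t.cpg_sites().tolist())
    total = sum(len(s) for s in cpg_by_target.values())
    if total == 0:
        raise ValueError("panel contains no CpG sites")
    hit: set[tuple[str, int]] = set()
    for m in mutations:
        sites = cpg_by_target.get(m.target)
        if sites is None:
            continue
        for pos in range(m.pos, m.pos + max(len(m.ref), 1)):
            if pos in sites:  # mutation at the C
                hit.add((m.target, pos))
            elif (pos - 1) in sites:  # mutation at the G
                hit.add((m.target, pos - 1))
    return len(hit) / total


def per_sample_channel_counts(mutations: list[MutationRecord]) -> pd.DataFrame:
    """Samples x 96-channel count table from deduplicated SNV calls."""
    counts: dict[str, dict[str, int]] = {}
    for m in mutations:
        ch = m.channel()
        if ch is not None:
            row = counts.setdefault(m.sample_id, {})
            row[ch] = row.get(ch, 0) + 1
    return (
        pd.DataFrame(counts).T.reindex(columns=list(CHANNELS_96)).fillna(0).sort_index()
    )


def spectrum96_to_frame(spectra: list[Spectrum96]) -> pd.DataFrame:
    return pd.DataFrame(
        {s.label or f"spectrum_{i}": s.values for i, s in enumerate(spectra)}
    ).rename_axis("channel")
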