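"""Cosine-similarity matching of observed spectra against signature catalogs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import SignatureCatalog
from .spectra import Spectrum96


@dataclass
class SimilarityReport:
    """Ranked cosine similarities of one query spectrum against a catalog."""

    query: str
    ranked: list[tuple[str, float]]  # (signature name, cosine), descending
    best_match: str
    ties: list[str]  # signatures within 1e-12 of the best cosine


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two equal-length nonnegative vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def match_catalog(spectrum: Spectrum96, catalog: SignatureCatalog) -> SimilarityReport:
    """Rank catalog signatures by cosine similarity to a query spectrum.

    The query is converted to proportions first (cosine itself is
    scale-free); ties are broken by catalog order and reported.
    """
    q = spectrum.as_proportions().values.to_numpy()
    cosines = [
        (name, cosine_similarity(q, catalog.matrix[i]))
        for i, name in enumerate(catalog.names)
    ]
    ranked = sorted(cosines, key=lambda t: -t[1])
    best_cos = ranked[0][1]
    # catalog order among the tied leaders decides best_match
    ties = [name for name, c in cosines if abs(c - best_cos) <= 1e-12]
    return SimilarityReport(
        query=spectrum.label or "query",
        ranked=ranked,
        best_match=ties[0],
        ties=ties,
    )
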