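"""Single-base-substitution signature catalogs (COSMIC-style 96-channel TSV)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import CHANNELS_96


@dataclass
class SignatureCatalog:
    """A set of named signatures, each a proportion vector over 96 channels.

    Rows of ``matrix`` are signatures in canonical COSMIC channel order and
    each sums to 1.
    """

    names: list[str]
    matrix: np.ndarray  # (n_signatures, 96)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.names), 96):
            raise ValueError(
                f"catalog matrix shape {self.matrix.shape} != ({len(self.names)}, 96)"
            )
        if (self.matrix < 0).any():
            raise ValueError("signature proportions must be nonnegative")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("each signature must sum to 1 within 1e-6")

    def __len__(self) -> int:
        return len(self.names)

    def signature(self, name: str) -> np.ndarray:
        return self.matrix[self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.T, index=list(CHANNELS_96), columns=self.names)


def read_signature_catalog(path) -> SignatureCatalog:
    """Read a catalog TSV: first column channel labels, one column per signature.

    Rows are reordered into canonical channel order.  Columns whose sums are
    off by at most 1e-3 are renormalized; larger deviations are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = set(df.index)
    expected = set(CHANNELS_96)
    if labels != expected:
        missing = sorted(expected - labels)[:5]
        extra = sorted(labels - expected)[:5]
        raise ValueError(
            f"catalog must have exactly the 96 canonical channels; "
            f"missing {missing}, unexpected {extra}"
        )
    df = df.loc[list(CHANNELS_96)]
    matrix = df.to_numpy(dtype=float).T
    if (matrix < 0).any():
        raise ValueError("negative value in signature catalog")
    sums = matrix.sum(axis=1)
    bad = np.abs(sums - 1.0) > 1e-3
    if bad.any():
        names = [df.columns[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"signature columns do not sum to 1 (off by >1e-3): {names}")
    matrix = matrix / sums[:, None]
    return SignatureCatalog(names=list(df.columns), matrix=matrix)


def write_signature_catalog(catalog: SignatureCatalog, path) -> None:
    catalog.to_frame().rename_axis("channel").to_csv(path, sep="\t")
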