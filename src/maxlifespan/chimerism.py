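"""Donor chimerism from per-image GFP+ nucleated-cell counts.

Bone-marrow chimerism — the fraction of a recipient's nucleated cells that
are donor-derived — is estimated by counting GFP-positive cells across
fluorescence images of a marrow preparation.  When the donor is heterozygous
for the GFP transgene only a fraction of its nucleated cells fluoresce
(25% in the reference strain), so the observed positive fraction must be
divided by that donor-positive reference fraction:

    chimerism = observed_fraction / donor_positive_fraction

e.g. 7% observed over 25% donor-positive gives 28% chimerism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "ChimerismImage",
    "ChimerismSample",
    "fraction_positive",
    "chimerism_corrected",
    "estimate_chimerism",
    "read_counts_csv",
    "write_counts_csv",
]


@dataclass(frozen=True)
class ChimerismImage:
    image_id: str
    n_positive: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_total < 0:
            raise ValueError(f"image {self.image_id!r}: counts must be >= 0")
        if self.n_positive > self.n_total:
            raise ValueError(
                f"image {self.image_id!r}: n_positive ({self.n_positive}) exceeds "
                f"n_total ({self.n_total})"
            )


@dataclass(frozen=True)
class ChimerismSample:
    """Per-image positive/total counts for one preparation, plus the donor reference."""

    sample_id: str
    images: tuple[ChimerismImage, ...]
    donor_positive_fraction: float = 0.25

    def __post_init__(self) -> None:
        object.__setattr__(self, "images", tuple(self.images))
        if not 0 < self.donor_positive_fraction <= 1:
            raise ValueError("donor_positive_fraction must lie in (0, 1]")


def fraction_positive(sample: ChimerismSample, mode: str = "mean_of_images") -> float:
    """Observed GFP+ fraction: unweighted mean of per-image fractions, or pooled counts."""
    nonempty = [im for im in sample.images if im.n_total > 0]
    if not nonempty:
        raise ValueError(f"sample {sample.sample_id!r}: no image with cells counted")
    if mode == "mean_of_images":
        return float(sum(im.n_positive / im.n_total for im in nonempty) / len(nonempty))
    if mode == "pooled":
        return float(sum(im.n_positive for im in nonempty) / sum(im.n_total for im in nonempty))
    raise ValueError(f"unknown mode {mode!r}")


def chimerism_corrected(
    observed_fraction: float,
    donor_positive_fraction: float,
    background_fraction: float = 0.0,
) -> float:
    """Correct the observed positive fraction for a partially expressing donor.

    Optionally subtracts an autofluorescence background (measured on
    GFP-negative control marrow; default 0) before dividing by the
    donor-positive reference fraction.
    """
    if not 0 <= observed_fraction <= 1:
        raise ValueError("observed_fraction must lie in [0, 1]")
    if not 0 < donor_positive_fraction <= 1:
        raise ValueError("donor_positive_fraction must lie in (0, 1]")
    if not 0 <= background_fraction <= observed_fraction and background_fraction != 0:
        raise ValueError("background_fraction must lie in [0, observed_fraction]")
    out = (observed_fraction - background_fraction) / donor_positive_fraction
    if out > 1 + 1e-9:
        raise ValueError(
            f"observed fraction {observed_fraction} exceeds donor ceiling "
            f"{donor_positive_fraction}: inconsistent inputs"
        )
    return min(out, 1.0)


def estimate_chimerism(sample: ChimerismSample, mode: str = "mean_of_images") -> float:
    """Full pipeline for one sample: observed fraction, then donor correction."""
    return chimerism_corrected(fraction_positive(sample, mode), sample.donor_positive_fraction)


_COLUMNS = ["sample_id", "image_id", "n_positive", "n_total"]


def read_counts_csv(
    path: str | Path, donor_positive_fraction: float = 0.25
) -> list[ChimerismSample]:
    """Read per-image counts (columns sample_id, image_id, n_positive, n_total)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "image_id": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    samples = []
    for sid, grp in df.groupby("sample_id", sort=True):
        images = []
        for i, row in enumerate(grp.itertuples(index=False), start=1):
            try:
                images.append(
                    ChimerismImage(str(row.image_id), int(row.n_positive), int(row.n_total))
                )
            except ValueError as exc:
                raise ValueError(f"{path}: sample {sid!r}: {exc}") from exc
        samples.append(
            ChimerismSample(str(sid), tuple(images), donor_positive_fraction)
        )
    return samples


def write_counts_csv(samples: list[ChimerismSample], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "image_id": im.image_id,
                "n_positive": im.n_positive,
                "n_total": im.n_total,
            }
            for s in samples
            for im in s.images
        ],
        columns=_COLUMNS,
    ).to_csv(path, index=False)
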