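"""Leaf-clip spectroradiometer spectra: splice correction, QC, averaging.

A field spectroradiometer reads 350-2500 nm through three internal
detectors whose segments can drift apart thermally, leaving offsets at
the detector junctions (nominally 1000 and 1800 nm).  Splice
correction shifts the outer segments additively so they meet the
central (NIR) detector's linear trend — the NIR detector is the
reference.  Replicate QC then (a) rejects replicates whose 450 nm
reflectance is abnormally high (light leaking past the leaf-clip
seal), (b) rejects replicates deviating from the replicate mean by
more than 2 percentage points of reflectance on average, and (c)
rejects the whole leaf when fewer than four viable replicates remain.
QC only flags replicates; it never modifies spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reflectance import Spectrum

__all__ = [
    "LeafSample",
    "splice_correct",
    "qc_replicates",
    "average_leaves_to_plot",
    "DEFAULT_JUNCTIONS_NM",
    "SEAL_CHECK_R450_MAX",
    "DEVIATION_MAX",
    "MIN_VIABLE",
]

DEFAULT_JUNCTIONS_NM = (1000.0, 1800.0)
SEAL_CHECK_R450_MAX = 0.10  # reflectance at 450 nm above this = bad clip seal
DEVIATION_MAX = 0.02  # mean |dev| from replicate mean, reflectance units
MIN_VIABLE = 4


@dataclass
class LeafSample:
    """One leaf's replicate spectra (nominally six) plus QC state."""

    leaf_id: str
    plot_id: str
    replicates: list[Spectrum]
    viable: list[bool] = field(default_factory=list)
    mean_spectrum: Spectrum | None = None
    qc_reasons: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("a leaf sample needs at least one replicate")
        if not self.viable:
            self.viable = [True] * len(self.replicates)
        if len(self.viable) != len(self.replicates):
            raise ValueError("viable flags must match replicate count")

    @property
    def accepted(self) -> bool:
        return self.mean_spectrum is not None

    @property
    def n_viable(self) -> int:
        return sum(self.viable)


def _segment_slices(
    wl: np.ndarray, junctions: tuple[float, ...]
) -> list[np.ndarray]:
    """Index masks for detector segments split at the junctions; the
    junction band belongs to the lower segment."""
    edges = (-np.inf, *junctions, np.inf)
    return [
        np.flatnonzero((wl > lo) & (wl <= hi))
        for lo, hi in zip(edges[:-1], edges[1:])
    ]


def splice_correct(
    s: Spectrum,
    junctions_nm: tuple[float, float] = DEFAULT_JUNCTIONS_NM,
    n_fit: int = 5,
) -> Spectrum:
    """Additively align the outer detector segments to the central
    (NIR) reference segment.

    For each junction, a straight line is fitted to the ``n_fit``
    reference-segment bands nearest the junction and extrapolated to
    the outer segment's boundary band; the whole outer segment is then
    shifted by the gap.  The reference segment is never changed, so
    applying the correction twice equals applying it once.
    """
    wl = s.wavelengths_nm
    for j in junctions_nm:
        if not (wl[0] < j < wl[-1]):
            raise ValueError(f"junction {j} nm outside the spectral grid")
    segs = _segment_slices(wl, tuple(sorted(junctions_nm)))
    if len(segs) != 3 or any(seg.size == 0 for seg in segs):
        raise ValueError("junctions must split the grid into three segments")
    lo_seg, ref_seg, hi_seg = segs
    values = s.values.copy()

    def linear_extrap(idx: np.ndarray, x: float) -> float:
        coeff = np.polyfit(wl[idx], values[idx], 1)
        return float(np.polyval(coeff, x))

    # lower (VNIR) segment: match its last band to the line through the
    # first n_fit reference bands
    pred = linear_extrap(ref_seg[:n_fit], wl[lo_seg[-1]])
    values[lo_seg] += pred - values[lo_seg[-1]]
    # upper (SWIR2) segment: match its first band to the line through
    # the last n_fit reference bands
    pred = linear_extrap(ref_seg[-n_fit:], wl[hi_seg[0]])
    values[hi_seg] += pred - values[hi_seg[0]]
    return Spectrum(wavelengths_nm=wl, values=values, unit=s.unit)


def qc_replicates(
    sample: LeafSample,
    seal_r450_max: float = SEAL_CHECK_R450_MAX,
    deviation_max: float = DEVIATION_MAX,
    min_viable: int = MIN_VIABLE,
) -> LeafSample:
    """Single-pass replicate QC; see module docstring for the rules.

    Rejection is a recorded state, not an error: a rejected leaf simply
    carries no mean spectrum.
    """
    wl = sample.replicates[0].wavelengths_nm
    for r in sample.replicates[1:]:
        if not np.array_equal(r.wavelengths_nm, wl):
            raise ValueError("replicates must share one wavelength grid")
    i450 = int(np.argmin(np.abs(wl - 450.0)))
    viable = list(sample.viable)
    reasons: dict[int, str] = {}

    for i, r in enumerate(sample.replicates):
        if viable[i] and r.values[i450] > seal_r450_max:
            viable[i] = False
            reasons[i] = (
                f"high light at 450 nm (R={r.values[i450]:.3f} > "
                f"{seal_r450_max}): leaf clip not sealed"
            )

    survivors = [i for i, v in enumerate(viable) if v]
    if survivors:
        stack = np.stack([sample.replicates[i].values for i in survivors])
        ref_mean = stack.mean(axis=0)
        for i in survivors:
            mad = float(np.mean(np.abs(sample.replicates[i].values - ref_mean)))
            if mad > deviation_max:
                viable[i] = False
                reasons[i] = (
                    f"mean deviation from replicate mean {mad:.4f} > "
                    f"{deviation_max} reflectance units"
                )

    kept = [i for i, v in enumerate(viable) if v]
    mean_spectrum = None
    if len(kept) >= min_viable:
        stack = np.stack([sample.replicates[i].values for i in kept])
        mean_spectrum = Spectrum(
            wavelengths_nm=wl,
            values=stack.mean(axis=0),
            unit=sample.replicates[0].unit,
        )
    return LeafSample(
        leaf_id=sample.leaf_id,
        plot_id=sample.plot_id,
        replicates=sample.replicates,
        viable=viable,
        mean_spectrum=mean_spectrum,
        qc_reasons=reasons,
    )


def average_leaves_to_plot(samples: list[LeafSample]) -> Spectrum:
    """Unweighted mean spectrum over the accepted leaves of one plot.

    The same unweighted averaging applies to the plot's ground-truth
    trait values (the trait table is averaged the same way upstream of
    model training).
    """
    accepted = [s for s in samples if s.accepted]
    if not accepted:
        ids = [s.leaf_id for s in samples]
        raise ValueError(f"no accepted leaves in plot (leaves: {ids})")
    wl = accepted[0].mean_spectrum.wavelengths_nm
    stack = np.stack([s.mean_spectrum.values for s in accepted])
    return Spectrum(
        wavelengths_nm=wl,
        values=stack.mean(axis=0),
        unit=accepted[0].mean_spectrum.unit,
    )
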