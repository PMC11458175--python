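"""Synthetic two-tissue phantom and scan-rescan map generator.

Every other module is testable without any external download: the phantom
instantiates the normalised sub-diffusion forward model voxel by voxel on a
small grid with two tissue classes (idealised white and grey matter), adds
powder-average-level Gaussian noise, and emits ground-truth parameter maps
alongside the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import AcquisitionScheme, SubDiffParams, connectome_scheme, k_star
from .simulate import GM_TRUTH, WM_TRUTH, noise_sigma, simulate_signal
from .volume_io import DWIDataset

__all__ = ["PhantomSpec", "make_phantom", "make_scan_rescan"]


@dataclass
class PhantomSpec:
    """Recipe for a synthetic DWI phantom.

    ``tissues`` maps integer region labels to sub-diffusion truths; the
    default two classes are the idealised white-matter (D_beta = 3e-4,
    beta = 0.75, K* = 0.8125) and grey-matter (5e-4, 0.85, 0.4733) pairs,
    laid out as a checkerboard.  ``snr`` of None means noiseless.
    The default 8 x 8 x 2 grid keeps full voxelwise fits at seconds scale.
    """

    shape: tuple[int, int, int] = (8, 8, 2)
    tissues: dict[int, SubDiffParams] = field(
        default_factory=lambda: {1: WM_TRUTH, 2: GM_TRUTH})
    scheme: AcquisitionScheme | None = None
    snr: float | None = None
    n_dirs: int = 64
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be a 3-tuple of positive sizes")
        if not self.tissues:
            raise ValueError("need at least one tissue class")
        if self.scheme is None:
            self.scheme = connectome_scheme(n_dirs=self.n_dirs)


def _checkerboard_labels(shape, labels) -> np.ndarray:
    ii, jj, kk = np.indices(shape)
    order = sorted(labels)
    return np.asarray(order)[(ii + jj + kk) % len(order)]


def make_phantom(spec: PhantomSpec) -> tuple[DWIDataset, dict[str, np.ndarray]]:
    """Build the phantom dataset and its ground-truth maps.

    Returns ``(dataset, truth)`` where ``truth`` holds 3-D maps ``Dbeta``,
    ``beta``, ``Kstar`` and the integer ``labels``.  Signals are
    powder-average-level values per (b, Delta) volume; with ``snr`` set,
    zero-mean Gaussian noise of SD ``1/(snr*sqrt(n_dirs))`` is added to
    every DW volume.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _checkerboard_labels(spec.shape, spec.tissues)
    scheme = spec.scheme
    sigma = 0.0 if spec.snr is None else noise_sigma(spec.snr, spec.n_dirs)

    data = np.empty(spec.shape + (len(scheme),))
    truth = {
        "Dbeta": np.empty(spec.shape),
        "beta": np.empty(spec.shape),
        "Kstar": np.empty(spec.shape),
    }
    clean_by_label = {
        lab: simulate_signal(p, scheme, 0.0, rng)
        for lab, p in spec.tissues.items()
    }
    for idx in np.ndindex(spec.shape):
        lab = int(labels[idx])
        p = spec.tissues[lab]
        sig = clean_by_label[lab]
        if sigma > 0:
            sig = sig + rng.normal(0.0, sigma, size=sig.shape)
            sig[scheme.is_b0] = 1.0
        data[idx] = sig
        truth["Dbeta"][idx] = p.d_beta
        truth["beta"][idx] = p.beta
        truth["Kstar"][idx] = k_star(p.beta)
    truth["labels"] = labels
    ds = DWIDataset(data=data, scheme=scheme, affine=np.eye(4),
                    mask=np.ones(spec.shape, dtype=bool), labels=labels)
    return ds, truth


def make_scan_rescan(spec: PhantomSpec, n_subjects: int, between_sd: float,
                     within_sd: float, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Paired per-subject K* maps exercising the ICC machinery.

    Each subject's map is the phantom's true K* map plus an independent
    per-voxel subject effect of SD ``between_sd``; scan and rescan then
    deviate from the subject mean by +/- one draw of SD ``within_sd``
    (the paired deviations are antithetic, so the subject mean is exact and
    the classical variance decomposition recovers the nominal ratio:
    expected ICC = between^2 / (between^2 + within^2)).

    Returns ``(scan, rescan)`` arrays of shape ``(n_subjects, *grid)``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if between_sd < 0 or within_sd < 0:
        raise ValueError("variance components must be non-negative")
    rng = np.random.default_rng(seed)
    labels = _checkerboard_labels(spec.shape, spec.tissues)
    base = np.zeros(spec.shape)
    for lab, p in spec.tissues.items():
        base[labels == lab] = k_star(p.beta)
    subj = base[None] + rng.normal(0.0, between_sd,
                                   size=(n_subjects,) + spec.shape)
    dev = rng.normal(0.0, within_sd, size=(n_subjects,) + spec.shape)
    return subj + dev, subj - dev
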