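"""Fusion-quality metrics: CC, RMSE, PSNR and joint entropy.

A fused image has no single reference, so each metric is computed against
each source separately and the headline value is the mean of the two
per-source terms (the per-source sub-scores are always reported so other
conventions can be recomputed):

* **CC** — Pearson correlation between the flattened all-channel pixel
  vectors of fused and source;
* **RMSE** — root-mean-square pixel difference over all channels, on the
  unit intensity range;
* **PSNR** — 20·log10(peak / RMSE) in dB, peak 1.0 on unit-range floats;
* **Joint entropy** — Shannon entropy (base 2) of the 2-D joint histogram
  of channel-mean luminance, 256×256 bins by default.  Higher means the
  pair carries more combined information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MetricReport", "cc", "rmse", "psnr", "joint_entropy", "evaluate"]

#: Sentinel used for an infinite PSNR term (identical images).
PSNR_CAP = 300.0


def _check(F, *sources):
    F = np.asarray(F, dtype=float)
    out = [F]
    for S in sources:
        S = np.asarray(S, dtype=float)
        if S.shape != F.shape:
            raise ValueError(f"shape mismatch: {F.shape} vs {S.shape}")
        out.append(S)
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x.ravel() - x.mean()
    y = y.ravel() - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("correlation undefined for a zero-variance image")
    return float(x @ y / (nx * ny))


def cc(F, S1, S2) -> float:
    """Mean Pearson correlation of the fused image with each source."""
    F, S1, S2 = _check(F, S1, S2)
    return 0.5 * (_pearson(F, S1) + _pearson(F, S2))


def _rmse_one(F, S) -> float:
    return float(np.sqrt(np.mean((F - S) ** 2)))


def rmse(F, S1, S2) -> float:
    """Mean over sources of the all-channel root-mean-square difference."""
    F, S1, S2 = _check(F, S1, S2)
    return 0.5 * (_rmse_one(F, S1) + _rmse_one(F, S2))


def _psnr_one(F, S, peak: float) -> tuple:
    r = _rmse_one(F, S)
    if r == 0.0:
        return PSNR_CAP, True
    return float(20.0 * np.log10(peak / r)), False


def psnr(F, S1, S2, peak: float = 1.0, return_flag: bool = False):
    """Mean over sources of 20·log10(peak/RMSE), in dB.

    An identical pair gives an infinite term, reported as the 300 dB cap;
    with ``return_flag=True`` the second return value says whether any term
    was capped.
    """
    F, S1, S2 = _check(F, S1, S2)
    p1, f1 = _psnr_one(F, S1, peak)
    p2, f2 = _psnr_one(F, S2, peak)
    value = 0.5 * (p1 + p2)
    return (value, f1 or f2) if return_flag else value


def _luminance(X: np.ndarray) -> np.ndarray:
    return X.mean(axis=-1) if X.ndim == 3 else X


def _joint_entropy_pair(F, S, bins: int) -> float:
    h, _, _ = np.histogram2d(
        _luminance(F).ravel(), _luminance(S).ravel(), bins=bins, range=[[0.0, 1.0], [0.0, 1.0]]
    )
    p = h / h.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def joint_entropy(F, S1, S2, bins: int = 256) -> float:
    """Mean over sources of the joint Shannon entropy H(F, S) in bits.

    Images are reduced to channel-mean luminance and co-binned on a
    bins×bins histogram over [0, 1].  Symmetric in its two images per term.
    """
    F, S1, S2 = _check(F, S1, S2)
    return 0.5 * (_joint_entropy_pair(F, S1, bins) + _joint_entropy_pair(F, S2, bins))


@dataclass
class MetricReport:
    """All four metrics plus per-source sub-scores and parameters."""

    cc: float
    rmse: float
    psnr: float
    joint_entropy: float
    per_source: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    psnr_capped: bool = False

    def to_dict(self) -> dict:
        return {
            "cc": self.cc,
            "rmse": self.rmse,
            "psnr": self.psnr,
            "joint_entropy": self.joint_entropy,
            "psnr_capped": self.psnr_capped,
            "per_source": self.per_source,
            "parameters": self.parameters,
        }


def evaluate(F, S1, S2, peak: float = 1.0, bins: int = 256) -> MetricReport:
    """Compute the full metric report of a fused image against its sources."""
    F, S1, S2 = _check(F, S1, S2)
    p1, f1 = _psnr_one(F, S1, peak)
    p2, f2 = _psnr_one(F, S2, peak)
    report = MetricReport(
        cc=cc(F, S1, S2),
        rmse=rmse(F, S1, S2),
        psnr=0.5 * (p1 + p2),
        joint_entropy=joint_entropy(F, S1, S2, bins),
        psnr_capped=f1 or f2,
        per_source={
            "cc": [_pearson(F, S1), _pearson(F, S2)],
            "rmse": [_rmse_one(F, S1), _rmse_one(F, S2)],
            "psnr": [p1, p2],
            "joint_entropy": [_joint_entropy_pair(F, S1, bins), _joint_entropy_pair(F, S2, bins)],
        },
        parameters={"peak": peak, "bins": bins},
    )
    return report
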