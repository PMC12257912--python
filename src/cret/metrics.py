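"""Image-fidelity metrics and the machine-readable evaluation report."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from typing import List

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["psnr", "ssim", "EvalRow", "EvalReport", "PSNR_CAP_DB"]

#: sentinel reported for identical images (MSE = 0)
PSNR_CAP_DB = 99.0


def psnr(a: np.ndarray, b: np.ndarray, data_range: float) -> float:
    """Peak signal-to-noise ratio, 10*log10(range^2 / MSE), dB; symmetric in
    (a, b); identical images report the capped sentinel."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(10.0 * np.log10(data_range**2 / mse), PSNR_CAP_DB)


def ssim(a: np.ndarray, b: np.ndarray, data_range: float, win_size: int = 7) -> float:
    """Structural similarity (standard windowed form, uniform window)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(structural_similarity(a, b, data_range=data_range,
                                       win_size=win_size))


@dataclass
class EvalRow:
    method: str
    binning: int
    phantom: int
    out_resolution: int
    psnr_db: float
    ssim: float
    failed: bool = False
    error: str = ""


@dataclass
class EvalReport:
    rows: List[EvalRow] = field(default_factory=list)
    data_range: float = 2000.0
    seed: int = 0
    params: dict = field(default_factory=dict)

    def add(self, **kw) -> None:
        self.rows.append(EvalRow(**kw))

    def mean(self, method: str, binning: int) -> float:
        vals = [r.psnr_db for r in self.rows
                if r.method == method and r.binning == binning and not r.failed]
        return float(np.mean(vals)) if vals else float("nan")

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump({"data_range": self.data_range, "seed": self.seed,
                       "params": self.params,
                       "rows": [asdict(r) for r in self.rows]}, f, indent=2)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as f:
            w = csv.DictWriter(f, fieldnames=list(asdict(EvalRow("", 0, 0, 0, 0.0, 0.0)).keys()))
            w.writeheader()
            for r in self.rows:
                w.writerow(asdict(r))
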