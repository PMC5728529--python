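"""Sliding-window detection of PTS (proline/threonine/serine-rich) regions.

Gel-forming mucins carry long low-complexity segments rich in Ser/Thr (the
O-glycosylation acceptor sites) and Pro.  Pfam has no model for these, so
they are detected compositionally: a window of ``window`` residues qualifies
when its combined Ser+Thr fraction strictly exceeds ``st_min_frac`` and its
Pro fraction is at least ``pro_min_frac``.  All qualifying windows whose
spans overlap or abut are merged into maximal regions.

Threshold strictness is deliberately asymmetric (strict ``>`` for Ser+Thr,
``>=`` for Pro).  ``X`` residues count toward window length but toward no
composition class.  Sequences shorter than the window yield no regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import ProteinRecord

__all__ = ["PtsParams", "PtsRegion", "window_qualifies", "scan_pts"]


@dataclass(frozen=True)
class PtsParams:
    """Parameters of the compositional window scan.

    window
        Window size in residues.
    st_min_frac
        Combined Ser+Thr fraction a window must strictly exceed.
    pro_min_frac
        Pro fraction a window must reach (inclusive).
    step
        Stride of the scan; 1 gives maximal sensitivity and is the
        setting under which region maximality is exact.
    combined_st
        When True (default) Ser and Thr are pooled into one fraction,
        the standard PTS reading; False requires one of the two residues
        alone to exceed the threshold (sensitivity-analysis mode).
    """

    window: int = 100
    st_min_frac: float = 0.40
    pro_min_frac: float = 0.05
    step: int = 1
    combined_st: bool = True

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        for name in ("st_min_frac", "pro_min_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class PtsRegion:
    """A maximal union of qualifying windows (1-based inclusive)."""

    protein_id: str
    start: int
    end: int
    st_frac_max: float
    pro_frac_max: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def window_qualifies(window_seq: str, params: PtsParams = PtsParams()) -> bool:
    """Decide whether one window of exactly ``params.window`` residues is PTS."""
    if len(window_seq) != params.window:
        raise ValueError(
            f"window sequence length {len(window_seq)} != window {params.window}"
        )
    w = params.window
    seq = window_seq.upper()
    n_s = seq.count("S")
    n_t = seq.count("T")
    n_p = seq.count("P")
    if params.combined_st:
        st_ok = (n_s + n_t) / w > params.st_min_frac
    else:
        st_ok = max(n_s, n_t) / w > params.st_min_frac
    return st_ok and n_p / w >= params.pro_min_frac


def scan_pts(protein: ProteinRecord, params: PtsParams = PtsParams()) -> list[PtsRegion]:
    """Scan a protein and return maximal PTS regions sorted by start.

    A sliding window of ``params.window`` residues moves with stride
    ``params.step``; qualifying windows whose spans overlap or abut are
    merged.  Implemented with cumulative residue counts so the scan is
    linear in sequence length.
    """
    seq = protein.sequence.upper()
    n = len(seq)
    w = params.window
    if n < w:
        return []

    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_s = np.cumsum(np.concatenate([[0], arr == ord("S")]))
    is_t = np.cumsum(np.concatenate([[0], arr == ord("T")]))
    is_p = np.cumsum(np.concatenate([[0], arr == ord("P")]))

    starts0 = np.arange(0, n - w + 1, params.step)  # 0-based window starts
    s_cnt = is_s[starts0 + w] - is_s[starts0]
    t_cnt = is_t[starts0 + w] - is_t[starts0]
    p_cnt = is_p[starts0 + w] - is_p[starts0]
    if params.combined_st:
        st_frac = (s_cnt + t_cnt) / w
    else:
        st_frac = np.maximum(s_cnt, t_cnt) / w
    pro_frac = p_cnt / w
    ok = (st_frac > params.st_min_frac) & (pro_frac >= params.pro_min_frac)

    regions: list[PtsRegion] = []
    cur_start = cur_end = -1  # 0-based span of the current merged region
    cur_st = cur_p = 0.0
    for i in np.flatnonzero(ok):
        ws, we = int(starts0[i]), int(starts0[i]) + w - 1
        if cur_start < 0 or ws > cur_end + 1:
            if cur_start >= 0:
                regions.append(
                    PtsRegion(protein.id, cur_start + 1, cur_end + 1, cur_st, cur_p)
                )
            cur_start, cur_end = ws, we
            cur_st, cur_p = float(st_frac[i]), float(pro_frac[i])
        else:
            cur_end = we
            cur_st = max(cur_st, float(st_frac[i]))
            cur_p = max(cur_p, float(pro_frac[i]))
    if cur_start >= 0:
        regions.append(
            PtsRegion(protein.id, cur_start + 1, cur_end + 1, cur_st, cur_p)
        )
    return regions
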