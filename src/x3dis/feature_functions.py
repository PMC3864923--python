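"""Parameterized residue feature-function families and featurization.

A feature function maps a residue position of a protein to a fixed-length
real vector.  Five families read the primary sequence alone; seven read a
per-residue annotation track (aa / pssm / ss3 / sa) through its probability
table p(i, l).  Windowed families are parameterized by a window size W; the
per-offset families (labels_local_window, separation_profile_window,
labeled_segments_window, dimeric_local_hist) require W odd so the window is
centred, while labels_local_hist accepts any W >= 1 (its published size
grid is 10..90) with offsets -((W-1)//2) .. +(W//2).

The separation-profile window is the distinctive encoding here: for every
label l it reports the sequence-separation distances from the residue of
interest to its nearest same-label residues on the N- and C-terminal sides,
laid out as a centred window, with missing slots filled by the farthest
available same-label distance on that side (or the protein length when a
side carries no such residue at all).  Applied to the solvent-accessibility
track it captures how far a residue sits from the nearest buried residue, a
quantity strongly associated with intrinsic disorder.

Feature vectors of several functions are combined by concatenation; the
resulting matrix has one row per residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from x3dis.protein_model import TRACK_ALPHABETS, AnnotationTrack, ProteinRecord

SEQUENCE_FAMILIES = (
    "num_residues",
    "num_cysteines",
    "unnorm_global_hist",
    "position",
    "relative_position",
)

ANNOTATION_FAMILIES = (
    "labels_global_hist",
    "labels_local_hist",
    "labels_local_window",
    "separation_profile_window",
    "labeled_segments_window",
    "dimeric_global_hist",
    "dimeric_local_hist",
)

#: Families whose window is a centred set of per-offset slots: W must be odd.
_ODD_WINDOW_FAMILIES = {
    "labels_local_window",
    "separation_profile_window",
    "labeled_segments_window",
    "dimeric_local_hist",
}

_WINDOWED_FAMILIES = _ODD_WINDOW_FAMILIES | {"labels_local_hist"}

#: Published window-size grids used by the default candidate enumeration.
WINDOW_GRID_LOCAL = (1, 5, 11, 15, 21)
WINDOW_GRID_HIST = (10, 20, 30, 40, 50, 60, 70, 80, 90)

_SPEC_RE = re.compile(r"^([a-z_]+?)(?:\(([a-z][a-z0-9]*)(?:,(\d+))?\))?$")


@dataclass(frozen=True, order=True)
class FeatureFunctionSpec:
    """One candidate feature function: family, source annotation, window size."""

    family: str
    annotation: str | None = None
    window: int | None = None

    def __post_init__(self) -> None:
        if self.family in SEQUENCE_FAMILIES:
            if self.annotation is not None or self.window is not None:
                raise ValueError(
                    f"{self.family} is sequence-level: no annotation or window"
                )
        elif self.family in ANNOTATION_FAMILIES:
            if self.annotation not in TRACK_ALPHABETS:
                raise ValueError(
                    f"{self.family} requires an annotation in "
                    f"{sorted(TRACK_ALPHABETS)}, got {self.annotation!r}"
                )
            if self.family in _WINDOWED_FAMILIES:
                if self.window is None or self.window < 1:
                    raise ValueError(f"{self.family} requires a window size >= 1")
                if self.family in _ODD_WINDOW_FAMILIES and self.window % 2 == 0:
                    raise ValueError(
                        f"{self.family} requires an odd window, got {self.window}"
                    )
            elif self.window is not None:
                raise ValueError(f"{self.family} takes no window parameter")
        else:
            raise ValueError(f"unknown feature family {self.family!r}")

    @property
    def n_labels(self) -> int:
        if self.annotation is None:
            raise ValueError(f"{self.family} has no annotation")
        return len(TRACK_ALPHABETS[self.annotation])

    @property
    def d(self) -> int:
        """Output dimensionality of this feature function."""
        fam = self.family
        if fam in ("num_residues", "num_cysteines", "position", "relative_position"):
            return 1
        if fam == "unnorm_global_hist":
            return 20
        L = self.n_labels
        if fam == "labels_global_hist":
            return L
        if fam == "labels_local_hist":
            return L + 1
        if fam in ("labels_local_window", "separation_profile_window"):
            return L * self.window
        if fam == "labeled_segments_window":
            return self.window * (L + 1)
        return L * L  # dimeric_global_hist / dimeric_local_hist

    def __str__(self) -> str:
        if self.annotation is None:
            return self.family
        if self.window is None:
            return f"{self.family}({self.annotation})"
        return f"{self.family}({self.annotation},{self.window})"

    @classmethod
    def parse(cls, text: str) -> "FeatureFunctionSpec":
        m = _SPEC_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse feature spec {text!r}")
        family, annotation, window = m.groups()
        return cls(family, annotation, int(window) if window is not None else None)

    def column_names(self) -> list[str]:
        return [f"{self}:{k}" for k in range(self.d)]


def _window_offsets(family: str, W: int) -> tuple[int, int]:
    """Inclusive offset range (lo, hi) covered by a window of size W."""
    if family in _ODD_WINDOW_FAMILIES or W % 2 == 1:
        K = (W - 1) // 2
        return -K, K
    return -((W - 1) // 2), W // 2


def _track(record: ProteinRecord, spec: FeatureFunctionSpec) -> AnnotationTrack:
    track = record.tracks.get(spec.annotation)
    if track is None:
        raise KeyError(
            f"protein {record.id!r} lacks annotation track {spec.annotation!r} "
            f"required by {spec}"
        )
    return track


def compute_feature(
    spec: FeatureFunctionSpec, record: ProteinRecord, i: int
) -> np.ndarray:
    """Evaluate one feature function at 1-based residue position ``i``."""
    n = record.n
    if not 1 <= i <= n:
        raise IndexError(f"position {i} out of range 1..{n}")
    fam = spec.family
    if fam == "num_residues":
        return np.array([float(n)])
    if fam == "num_cysteines":
        return np.array([float(record.sequence.count("C"))])
    if fam == "unnorm_global_hist":
        aa = record.tracks["aa"]
        return aa.probs.sum(axis=0)
    if fam == "position":
        return np.array([float(i)])
    if fam == "relative_position":
        return np.array([i / n])

    track = _track(record, spec)
    P = track.probs
    L = spec.n_labels
    if fam == "labels_global_hist":
        return P.mean(axis=0)
    if fam == "labels_local_hist":
        return _labels_local_hist(P, i - 1, spec.window)
    if fam == "labels_local_window":
        return _labels_local_window(P, i - 1, spec.window)
    if fam == "separation_profile_window":
        return _separation_profile_window(track.argmax_labels(), L, n, i - 1, spec.window)
    if fam == "labeled_segments_window":
        return _labeled_segments_window(track.argmax_labels(), L, i - 1, spec.window)
    if fam == "dimeric_global_hist":
        return _dimeric_global_hist(P)
    if fam == "dimeric_local_hist":
        return _dimeric_local_hist(P, i - 1, spec.window)
    raise AssertionError(f"unhandled family {fam}")


def _labels_local_hist(P: np.ndarray, i0: int, W: int) -> np.ndarray:
    n, L = P.shape
    lo_off, hi_off = _window_offsets("labels_local_hist", W)
    lo, hi = i0 + lo_off, i0 + hi_off  # inclusive
    in_lo, in_hi = max(lo, 0), min(hi, n - 1)
    out = np.zeros(L + 1)
    if in_lo <= in_hi:
        out[:L] = P[in_lo : in_hi + 1].sum(axis=0) / W
    out[L] = (W - max(0, in_hi - in_lo + 1)) / W
    return out


def _labels_local_window(P: np.ndarray, i0: int, W: int) -> np.ndarray:
    n, L = P.shape
    K = (W - 1) // 2
    out = np.zeros((W, L))
    lo, hi = max(i0 - K, 0), min(i0 + K, n - 1)
    if lo <= hi:
        out[lo - (i0 - K) : hi - (i0 - K) + 1] = P[lo : hi + 1]
    return out.ravel()  # offset-major, label-minor


def _separation_profile_window(
    lab: np.ndarray, L: int, n: int, i0: int, W: int
) -> np.ndarray:
    K = (W - 1) // 2
    out = np.empty((L, W))
    for l in range(L):
        pos = np.flatnonzero(lab == l)
        left = pos[pos < i0]  # ascending
        right = pos[pos > i0]
        # N-terminal side, slots -K..-1: farthest of the K nearest first.
        ldist = (i0 - left)[::-1]  # nearest first
        lslots = np.empty(K)
        if ldist.size == 0:
            lslots[:] = n
        else:
            k = min(K, ldist.size)
            lslots[:k] = ldist[:k]
            lslots[k:] = ldist.max()  # fill: farthest same-label distance, N side
        # C-terminal side, slots +1..+K: nearest first.
        rdist = right - i0
        rslots = np.empty(K)
        if rdist.size == 0:
            rslots[:] = n
        else:
            k = min(K, rdist.size)
            rslots[:k] = rdist[:k]
            if k < K:
                rslots[k:] = rdist.max()
        if lab[i0] == l:
            centre = 0.0
        elif ldist.size or rdist.size:
            centre = min(
                ldist[0] if ldist.size else n, rdist[0] if rdist.size else n
            )
        else:
            centre = n
        out[l, :K] = lslots[::-1]  # slot -K holds the farthest of the K
        out[l, K] = centre
        out[l, K + 1 :] = rslots
    return out.ravel()  # label-major blocks of W slots each


def _segments(lab: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length segmentation: (segment label, length, per-residue segment idx)."""
    n = lab.size
    change = np.flatnonzero(np.diff(lab)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    seg_idx = np.zeros(n, dtype=int)
    seg_idx[starts[1:]] = 1
    seg_idx = np.cumsum(seg_idx)
    return lab[starts], ends - starts, seg_idx


def _labeled_segments_window(lab: np.ndarray, L: int, i0: int, W: int) -> np.ndarray:
    K = (W - 1) // 2
    seg_lab, seg_len, seg_idx = _segments(lab)
    s0 = seg_idx[i0]
    out = np.zeros((W, L + 1))
    for j, delta in enumerate(range(-K, K + 1)):
        s = s0 + delta
        if 0 <= s < seg_lab.size:
            out[j, seg_lab[s]] = 1.0
            out[j, L] = seg_len[s]
    return out.ravel()


def _dimeric_global_hist(P: np.ndarray) -> np.ndarray:
    n, L = P.shape
    if n < 2:
        return np.zeros(L * L)
    return (P[:-1].T @ P[1:]).ravel() / (n - 1)


def _dimeric_local_hist(P: np.ndarray, i0: int, W: int) -> np.ndarray:
    n, L = P.shape
    if W == 1:
        return np.zeros(L * L)
    K = (W - 1) // 2
    lo, hi = max(i0 - K, 0), min(i0 + K, n - 1)
    if hi - lo < 1:
        return np.zeros(L * L)
    block = P[lo : hi + 1]
    return (block[:-1].T @ block[1:]).ravel() / (W - 1)


# --- vectorized per-protein evaluation -------------------------------------


def compute_feature_block(spec: FeatureFunctionSpec, record: ProteinRecord) -> np.ndarray:
    """All-residue feature matrix (n, spec.d) for one protein.

    Equivalent to stacking :func:`compute_feature` over every position, but
    vectorized for the families where that matters.
    """
    n = record.n
    fam = spec.family
    if fam in ("num_residues", "num_cysteines", "unnorm_global_hist",
               "labels_global_hist", "dimeric_global_hist"):
        row = compute_feature(spec, record, 1)
        return np.broadcast_to(row, (n, row.size)).copy()
    if fam == "position":
        return np.arange(1.0, n + 1.0)[:, None]
    if fam == "relative_position":
        return (np.arange(1.0, n + 1.0) / n)[:, None]
    if fam == "labels_local_window":
        P = _track(record, spec).probs
        W = spec.window
        K = (W - 1) // 2
        Ppad = np.vstack([np.zeros((K, P.shape[1])), P, np.zeros((K, P.shape[1]))])
        windows = np.lib.stride_tricks.sliding_window_view(Ppad, W, axis=0)
        # windows: (n, L, W) -> offset-major (n, W, L)
        return windows.transpose(0, 2, 1).reshape(n, -1)
    if fam == "labels_local_hist":
        return _labels_local_hist_block(_track(record, spec).probs, spec.window)
    if fam == "separation_profile_window":
        track = _track(record, spec)
        return _separation_profile_block(
            track.argmax_labels(), spec.n_labels, n, spec.window
        )
    if fam == "labeled_segments_window":
        track = _track(record, spec)
        return _labeled_segments_block(track.argmax_labels(), spec.n_labels, spec.window)
    if fam == "dimeric_local_hist":
        return _dimeric_local_hist_block(_track(record, spec).probs, spec.window)
    return np.stack([compute_feature(spec, record, i) for i in range(1, n + 1)])


def _labels_local_hist_block(P: np.ndarray, W: int) -> np.ndarray:
    n, L = P.shape
    lo_off, hi_off = _window_offsets("labels_local_hist", W)
    csum = np.vstack([np.zeros(L), np.cumsum(P, axis=0)])
    i = np.arange(n)
    lo = np.clip(i + lo_off, 0, n)  # inclusive start
    hi = np.clip(i + hi_off + 1, 0, n)  # exclusive end
    sums = csum[hi] - csum[lo]
    in_bounds = hi - lo
    out = np.empty((n, L + 1))
    out[:, :L] = sums / W
    out[:, L] = (W - in_bounds) / W
    return out


def _separation_profile_block(lab: np.ndarray, L: int, n: int, W: int) -> np.ndarray:
    K = (W - 1) // 2
    i = np.arange(n)
    out = np.empty((n, L, W))
    for l in range(L):
        pos = np.flatnonzero(lab == l)
        m = pos.size
        if m == 0:
            out[:, l, :] = n
            continue
        # count of same-label positions strictly left of i
        n_left = np.searchsorted(pos, i, side="left")
        # exclude i itself from the right side
        n_le = np.searchsorted(pos, i, side="right")
        n_right = m - n_le
        left_far = np.where(n_left > 0, i - pos[0], n)
        right_far = np.where(n_right > 0, pos[-1] - i, n)
        for k in range(1, K + 1):
            j = n_left - k
            lk = np.where(j >= 0, i - pos.take(np.clip(j, 0, m - 1)), left_far)
            out[:, l, K - k] = lk
            j = n_le + k - 1
            rk = np.where(j < m, pos.take(np.clip(j, 0, m - 1)) - i, right_far)
            out[:, l, K + k] = rk
        near = np.minimum(
            np.where(n_left > 0, i - pos.take(np.clip(n_left - 1, 0, m - 1)), n),
            np.where(n_right > 0, pos.take(np.clip(n_le, 0, m - 1)) - i, n),
        )
        out[:, l, K] = np.where(lab == l, 0, near)
    return out.reshape(n, L * W)


def _labeled_segments_block(lab: np.ndarray, L: int, W: int) -> np.ndarray:
    n = lab.size
    K = (W - 1) // 2
    seg_lab, seg_len, seg_idx = _segments(lab)
    S = seg_lab.size
    out = np.zeros((n, W, L + 1))
    for j, delta in enumerate(range(-K, K + 1)):
        s = seg_idx + delta
        ok = (s >= 0) & (s < S)
        sc = np.clip(s, 0, S - 1)
        rows = np.flatnonzero(ok)
        out[rows, j, seg_lab[sc[ok]]] = 1.0
        out[rows, j, L] = seg_len[sc[ok]]
    return out.reshape(n, W * (L + 1))


def _dimeric_local_hist_block(P: np.ndarray, W: int) -> np.ndarray:
    n, L = P.shape
    if W == 1 or n < 2:
        return np.zeros((n, L * L))
    K = (W - 1) // 2
    pairs = (P[:-1, :, None] * P[1:, None, :]).reshape(n - 1, L * L)
    csum = np.vstack([np.zeros(L * L), np.cumsum(pairs, axis=0)])
    i = np.arange(n)
    # pair j covers residues (j, j+1); in-window pairs are j in [i-K, i+K-1]
    lo = np.clip(i - K, 0, n - 1)
    hi = np.clip(i + K, 0, n - 1)  # exclusive pair index end
    return (csum[hi] - csum[lo]) / (W - 1)


def featurize(
    records: Sequence[ProteinRecord],
    encoding: Sequence[FeatureFunctionSpec],
) -> pd.DataFrame:
    """Concatenate feature-function outputs for every residue of a corpus.

    Returns a DataFrame with a (protein id, 1-based position) MultiIndex and
    one column per feature, named "family(annotation,W):k".
    """
    if not encoding:
        raise ValueError("empty encoding")
    blocks = []
    index = []
    for rec in records:
        per_spec = [compute_feature_block(spec, rec) for spec in encoding]
        blocks.append(np.hstack(per_spec))
        index.extend((rec.id, i) for i in range(1, rec.n + 1))
    values = np.vstack(blocks)
    if not np.isfinite(values).all():
        raise ValueError("featurization produced non-finite values")
    columns = [name for spec in encoding for name in spec.column_names()]
    return pd.DataFrame(
        values,
        index=pd.MultiIndex.from_tuples(index, names=["protein", "position"]),
        columns=columns,
    )


def enumerate_default_candidates() -> list[FeatureFunctionSpec]:
    """The default wrapper-selection grid of 109 candidate feature functions.

    Five sequence-level families, then for each annotation (aa, pssm, ss3,
    sa): the global histogram, nine local-histogram sizes, five local-window
    sizes, five separation-profile sizes, the dimeric global histogram and
    five dimeric local-histogram sizes.  labeled_segments_window is
    implemented but kept out of the default grid; add it explicitly when
    wanted.
    """
    out = [FeatureFunctionSpec(f) for f in SEQUENCE_FAMILIES]
    for annotation in ("aa", "pssm", "ss3", "sa"):
        out.append(FeatureFunctionSpec("labels_global_hist", annotation))
        out.extend(
            FeatureFunctionSpec("labels_local_hist", annotation, W)
            for W in WINDOW_GRID_HIST
        )
        out.extend(
            FeatureFunctionSpec("labels_local_window", annotation, W)
            for W in WINDOW_GRID_LOCAL
        )
        out.extend(
            FeatureFunctionSpec("separation_profile_window", annotation, W)
            for W in WINDOW_GRID_LOCAL
        )
        out.append(FeatureFunctionSpec("dimeric_global_hist", annotation))
        out.extend(
            FeatureFunctionSpec("dimeric_local_hist", annotation, W)
            for W in WINDOW_GRID_LOCAL
        )
    return out


def reduced_candidate_grid() -> list[FeatureFunctionSpec]:
    """A ~20-candidate grid for scaled-down selection experiments.

    Keeps at least one representative of every informative family per
    annotation so the wrapper still has to discriminate between genuinely
    competing encodings.
    """
    specs = [
        FeatureFunctionSpec("num_residues"),
        FeatureFunctionSpec("num_cysteines"),
        FeatureFunctionSpec("unnorm_global_hist"),
        FeatureFunctionSpec("relative_position"),
    ]
    for annotation in ("aa", "pssm", "ss3", "sa"):
        specs.append(FeatureFunctionSpec("labels_local_window", annotation, 5))
        specs.append(FeatureFunctionSpec("separation_profile_window", annotation, 11))
        specs.append(FeatureFunctionSpec("labels_local_hist", annotation, 30))
    specs.append(FeatureFunctionSpec("labels_local_window", "pssm", 11))
    specs.append(FeatureFunctionSpec("labels_local_window", "sa", 11))
    specs.append(FeatureFunctionSpec("dimeric_global_hist", "sa"))
    specs.append(FeatureFunctionSpec("dimeric_local_hist", "sa", 11))
    return specs
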