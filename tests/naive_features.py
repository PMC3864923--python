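"""Independent brute-force reference implementations of the feature families.

Deliberately written with plain Python loops, explicit run-length
segmentation and explicit pair enumeration, sharing no code with the
package implementation, so disagreements expose real defects.
"""

from __future__ import annotations

import numpy as np

from x3dis.protein_model import TRACK_ALPHABETS


def naive_feature(spec, record, i):
    """Evaluate feature function `spec` at 1-based position `i` by brute force."""
    fam = spec.family
    n = record.n
    if fam == "num_residues":
        return [float(n)]
    if fam == "num_cysteines":
        return [float(sum(1 for c in record.sequence if c == "C"))]
    if fam == "unnorm_global_hist":
        return [
            float(sum(1 for c in record.sequence if c == a))
            for a in TRACK_ALPHABETS["aa"]
        ]
    if fam == "position":
        return [float(i)]
    if fam == "relative_position":
        return [i / n]

    P = record.tracks[spec.annotation].probs
    L = P.shape[1]
    W = spec.window

    if fam == "labels_global_hist":
        return [sum(P[j, l] for j in range(n)) / n for l in range(L)]

    if fam == "labels_local_hist":
        left = (W - 1) // 2
        offsets = list(range(-left, W - left))
        out = [0.0] * (L + 1)
        oob = 0
        for delta in offsets:
            j = (i - 1) + delta
            if 0 <= j < n:
                for l in range(L):
                    out[l] += P[j, l] / W
            else:
                oob += 1
        out[L] = oob / W
        return out

    K = (W - 1) // 2 if W is not None else None

    if fam == "labels_local_window":
        out = []
        for delta in range(-K, K + 1):
            j = (i - 1) + delta
            for l in range(L):
                out.append(P[j, l] if 0 <= j < n else 0.0)
        return out

    # argmax labelling with earliest-label tie-break
    lab = [max(range(L), key=lambda l: (P[j, l], -l)) for j in range(n)]

    if fam == "separation_profile_window":
        i0 = i - 1
        out = []
        for l in range(L):
            where = [j for j in range(n) if lab[j] == l]
            left_d = sorted(i0 - j for j in where if j < i0)  # ascending
            right_d = sorted(j - i0 for j in where if j > i0)
            slots = [0.0] * W
            for k in range(1, K + 1):
                if k <= len(left_d):
                    v = left_d[k - 1]
                elif left_d:
                    v = max(left_d)
                else:
                    v = n
                slots[K - k] = float(v)
                if k <= len(right_d):
                    v = right_d[k - 1]
                elif right_d:
                    v = max(right_d)
                else:
                    v = n
                slots[K + k] = float(v)
            if lab[i0] == l:
                slots[K] = 0.0
            elif left_d or right_d:
                slots[K] = float(min(left_d + right_d))
            else:
                slots[K] = float(n)
            out.extend(slots)
        return out

    if fam == "labeled_segments_window":
        segments = []
        start = 0
        for j in range(1, n + 1):
            if j == n or lab[j] != lab[start]:
                segments.append((lab[start], j - start, start, j - 1))
                start = j
        s0 = next(
            k for k, (_, _, a, b) in enumerate(segments) if a <= i - 1 <= b
        )
        out = []
        for delta in range(-K, K + 1):
            s = s0 + delta
            if 0 <= s < len(segments):
                label, length, _, _ = segments[s]
                out.extend([1.0 if l == label else 0.0 for l in range(L)])
                out.append(float(length))
            else:
                out.extend([0.0] * (L + 1))
        return out

    if fam == "dimeric_global_hist":
        out = [0.0] * (L * L)
        if n < 2:
            return out
        for j in range(n - 1):
            for l1 in range(L):
                for l2 in range(L):
                    out[l1 * L + l2] += P[j, l1] * P[j + 1, l2] / (n - 1)
        return out

    if fam == "dimeric_local_hist":
        out = [0.0] * (L * L)
        if W == 1:
            return out
        i0 = i - 1
        for j in range(n - 1):
            if i0 - K <= j and j + 1 <= i0 + K:
                for l1 in range(L):
                    for l2 in range(L):
                        out[l1 * L + l2] += P[j, l1] * P[j + 1, l2] / (W - 1)
        return out

    raise ValueError(fam)
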