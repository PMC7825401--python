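"""Independent reference computations used only to check the package.

These deliberately avoid the code paths they validate: alignment scores by
exhaustive enumeration of every global alignment, sphere-overlap areas by
the closed-form spherical-cap formula, and RMSD floors by direct evaluation
under random rigid transforms.
"""

from __future__ import annotations

import math


def enumerate_alignment_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Maximum global alignment score by walking every alignment path.

    A gap of length L costs gap_open + (L - 1) * gap_extend.  Exponential in
    the sequence lengths; intended for sequences of length <= 8.
    """
    best = -math.inf

    def walk(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + float(matrix[a[i], b[j]]), "M")
        if i < len(a):
            cost = gap_extend if last == "X" else gap_open
            walk(i + 1, j, score - cost, "X")
        if j < len(b):
            cost = gap_extend if last == "Y" else gap_open
            walk(i, j + 1, score - cost, "Y")

    walk(0, 0, 0.0, "M")
    return best


def two_equal_spheres_buried_area(r_expanded: float, distance: float) -> float:
    """Total SASA lost when two equal expanded spheres overlap.

    Each sphere loses a spherical cap of area 2*pi*R*h with
    h = R - distance/2; zero when the spheres do not intersect.
    """
    if distance >= 2.0 * r_expanded:
        return 0.0
    h = r_expanded - distance / 2.0
    return 2.0 * (2.0 * math.pi * r_expanded * h)
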