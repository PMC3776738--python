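"""Brute-force definitional oracle for dispersion-threshold segmentation.

A deliberately naive re-statement of the sliding-window procedure using
plain Python lists and full recomputation at every step, kept independent of
the package implementation so the two can be compared on random streams:

* starting at the earliest unconsumed move, take the smallest window whose
  time span reaches the duration threshold;
* while that window's dispersion (x-range + y-range) exceeds the dispersion
  threshold, drop its first move and take the minimal window again;
* otherwise grow the window one move at a time until the next move would
  push the dispersion over the threshold;
* emit the window: centroid of member coordinates, start at the first
  member's timestamp, end at the violating move's timestamp (last member's
  timestamp + 1 when the stream ends first); resume at the violating move.
"""

from __future__ import annotations


def oracle_dispersion(points) -> float:
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    return (max(xs) - min(xs)) + (max(ys) - min(ys))


def oracle_segment(moves, dispersion_threshold: float = 6.0, duration_threshold: int = 20):
    """Return a list of dicts {cx, cy, start_t, end_t, members}."""
    moves = [(int(t), float(x), float(y)) for t, x, y in moves]
    out = []
    i = 0
    n = len(moves)
    while i < n:
        # minimal window reaching the duration threshold
        j = i
        while j < n and moves[j][0] - moves[i][0] < duration_threshold:
            j += 1
        if j >= n:
            break
        window = moves[i : j + 1]
        if oracle_dispersion([(m[1], m[2]) for m in window]) > dispersion_threshold:
            i += 1
            continue
        k = j + 1
        while k < n:
            candidate = moves[i : k + 1]
            if oracle_dispersion([(m[1], m[2]) for m in candidate]) > dispersion_threshold:
                break
            k += 1
        members = list(range(i, k))
        xs = [moves[m][1] for m in members]
        ys = [moves[m][2] for m in members]
        end_t = moves[k][0] if k < n else moves[n - 1][0] + 1
        out.append(
            {
                "cx": sum(xs) / len(xs),
                "cy": sum(ys) / len(ys),
                "start_t": moves[i][0],
                "end_t": end_t,
                "members": members,
            }
        )
        if k >= n:
            break
        i = k
    return out


def random_stream(rng, max_moves: int = 200):
    """Random screen-move stream mixing dwell clusters, travel and ties."""
    n_total = int(rng.integers(2, max_moves + 1))
    t = 0
    moves = []
    cx, cy = rng.uniform(0, 100, 2)
    while len(moves) < n_total:
        mode = rng.random()
        if mode < 0.55:  # dwell cluster near the current point
            for _ in range(int(rng.integers(1, 8))):
                moves.append(
                    (
                        t,
                        cx + rng.uniform(-2.5, 2.5),
                        cy + rng.uniform(-2.5, 2.5),
                    )
                )
                t += int(rng.integers(0, 15))  # zero steps create ties
        elif mode < 0.85:  # travel: scattered single moves
            cx, cy = rng.uniform(0, 100, 2)
            moves.append((t, cx, cy))
            t += int(rng.integers(1, 30))
        else:  # small drift, may straddle the dispersion cap
            cx += rng.uniform(-4, 4)
            cy += rng.uniform(-4, 4)
            moves.append((t, cx, cy))
            t += int(rng.integers(1, 10))
    return moves[:n_total]
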