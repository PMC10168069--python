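"""Brute-force oracle for the tiny fixture's expected MPD/CWM values.

Deliberately independent of the funcstruct package: plain double loops over
hard-coded tables, re-stating the fixture's numbers. Run from the repo root:

    python scripts/tiny_truth.py

and paste the printed dict into the tiny preset's truth record.
"""

import json

PLOTS = ["P1", "P2", "P3", "P4"]
SPECIES = ["sp1", "sp2", "sp3", "sp4", "sp5", "sp6"]
ABUNDANCE = {
    "P1": [4.0, 2.0, 0.0, 0.0, 1.0, 0.0],
    "P2": [0.0, 3.0, 3.0, 0.0, 0.0, 2.0],
    "P3": [1.0, 0.0, 2.0, 4.0, 2.0, 1.0],
    "P4": [0.0, 0.0, 0.0, 5.0, 0.0, 5.0],
}
TRAITS = {
    "LT": [0.2, 0.4, 0.6, 0.8, 1.0, 1.2],
    "SLA": [20.0, 16.0, 12.0, 10.0, 8.0, 6.0],
}


def gower_1d(values):
    rng = max(values) - min(values)
    return [[abs(a - b) / rng for b in values] for a in values]


def brute_mpd(cover, dist):
    present = [i for i, a in enumerate(cover) if a > 0]
    if len(present) < 2:
        return None
    total, pairs = 0.0, 0
    for i in present:
        for j in present:
            if i != j:
                total += dist[i][j]
                pairs += 1
    return total / pairs


def brute_cwm(cover, traits):
    tot = sum(cover)
    return sum(a * t for a, t in zip(cover, traits)) / tot


def main():
    out = {"MPD": {}, "CWM": {}}
    for trait, tvals in TRAITS.items():
        dist = gower_1d(tvals)
        out["MPD"][trait] = {p: brute_mpd(ABUNDANCE[p], dist) for p in PLOTS}
        out["CWM"][trait] = {p: brute_cwm(ABUNDANCE[p], tvals) for p in PLOTS}
    print(json.dumps(out, indent=2))
    for metric in out:
        for trait in out[metric]:
            for plot, v in out[metric][trait].items():
                print(f"{metric} {trait} {plot}: {v!r}")


if __name__ == "__main__":
    main()
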