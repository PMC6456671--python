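"""Genome-scale reproduction: feasibility boundaries of iJR904.

This run is NOT desk scale: it downloads the iJR904 model from the BiGG
database and solves genome-scale MILPs that can take hours per boundary
search, so it is shipped as a standalone script rather than a test.

It reproduces the reported boundaries for E. coli iJR904 on minimal glucose
medium:

* minimum T_IN for growth: 254 (K=1), 215 (K=2), 203 (K=3),
* minimum T_TR for growth: 9,
* 143 extracellular metabolites counted at load.

Usage::

    python scripts/reproduce_ijr904.py [--model PATH] [--time-limit SEC]
                                       [--mip-gap G] [--out results.json]

If ``--model`` is omitted the script downloads
http://bigg.ucsd.edu/static/models/iJR904.json (network access required).
Boundary values are sensitive to the MIP gap and time limit; the defaults
ask for a tight gap and give each solve a generous budget.
"""

from __future__ import annotations

import argparse
import json
import sys
import urllib.request

from dolmn import classify_reactions, load_model, min_feasible_T_IN, min_feasible_T_TR

BIGG_URL = "http://bigg.ucsd.edu/static/models/iJR904.json"

REPORTED = {
    "min_T_IN_K1": 254,
    "min_T_IN_K2": 215,
    "min_T_IN_K3": 203,
    "min_T_TR_K1": 9,
    "extracellular_metabolites": 143,
}


def fetch_model(path: str | None) -> str:
    if path:
        return path
    dest = "iJR904.json"
    print(f"downloading {BIGG_URL} -> {dest}", file=sys.stderr)
    urllib.request.urlretrieve(BIGG_URL, dest)
    return dest


def main(argv: list[str] | None = None) -> int:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--model", default=None, help="local iJR904 file (skips download)")
    ap.add_argument("--time-limit", type=float, default=3600.0,
                    help="seconds per MILP solve")
    ap.add_argument("--mip-gap", type=float, default=1e-3)
    ap.add_argument("--out", default="ijr904_boundaries.json")
    args = ap.parse_args(argv)

    model = load_model(fetch_model(args.model))
    cls = classify_reactions(model)
    results = {"extracellular_metabolites": cls.m_e}
    print(f"loaded: {model.m} metabolites, {model.n} reactions, "
          f"M_e={cls.m_e} (reported {REPORTED['extracellular_metabolites']})")

    for K in (1, 2, 3):
        val = min_feasible_T_IN(model, K, mip_gap=args.mip_gap,
                                time_limit=args.time_limit)
        results[f"min_T_IN_K{K}"] = val
        print(f"min T_IN (K={K}): {val} (reported {REPORTED[f'min_T_IN_K{K}']})")

    val = min_feasible_T_TR(model, 1, mip_gap=args.mip_gap,
                            time_limit=args.time_limit)
    results["min_T_TR_K1"] = val
    print(f"min T_TR (K=1): {val} (reported {REPORTED['min_T_TR_K1']})")

    with open(args.out, "w") as fh:
        json.dump({"computed": results, "reported": REPORTED}, fh, indent=1)
    print(f"written to {args.out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
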