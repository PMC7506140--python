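"""Relative stability (basin sizes) of coexisting phenotypes.

For every multistable model of a coupled-circuit ensemble, 1000 random
initial conditions are relaxed and arrivals per phenotype counted (three
independent batches for error bars).  Headlines: in {H,M} models the
hybrid state wins more often than the mesenchymal one; in {E,H,M} models
the epithelial basin is the smallest.
"""

from pathlib import Path

from emt_nfatc.ensemble import relative_stability, run_ensemble, stability_frame
from emt_nfatc.topology import wildtype_coupled

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    topo = wildtype_coupled()
    models = run_ensemble(topo, 2000, 100, seed=5)
    multis = [m for m in models if m.phase in ("EH", "HM", "EHM")]
    records = relative_stability(topo, multis, n_initial_conditions=1000,
                                 repeats=3, seed=7)
    sf = stability_frame(records)
    sf.to_csv(RESULTS / "relative_stability.csv", index=False)
    hm = sf[sf.phase == "HM"].groupby("model_id")[["n_H", "n_M"]].mean()
    print(f"{{H,M}} models: H deeper in {(hm.n_H > hm.n_M).sum()}, "
          f"M deeper in {(hm.n_M > hm.n_H).sum()}")
    ehm = sf[sf.phase == "EHM"].groupby("model_id")[["n_E", "n_H", "n_M"]].mean()
    if len(ehm):
        print("{E,H,M} models, mean arrivals:",
              ehm.mean().round(1).to_dict())


if __name__ == "__main__":
    main()
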