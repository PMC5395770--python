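#!/usr/bin/env python
"""Generate the synthetic study dataset.

Emulates the statistical structure of the resequencing panels the scan was
designed for: two cultivated groups with background diversities 0.00196
(japonica-like) and 0.00265 (indica-like), between-group divergence 0.00617,
a diverse wild pool (0.0067), an outgroup, and three implanted regions of
each domesticated-region type. Writes the VCF and companions under
scratch/analysis/sim and a realized-vs-target calibration table under
results/.
"""
import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ricesweep import io as rio
from ricesweep import scan as rscan
from ricesweep.simulate import SimParams, simulate

SIM_DIR = Path("scratch/analysis/sim")
RESULTS = Path("results")
SEED = 1


def main():
    params = SimParams(seed=SEED)
    res = simulate(params, SIM_DIR)
    st = rio.SampleTable.from_tsv(res.sample_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm = rio.read_vcf(res.vcf_path, st)

    rows = []
    targets = {"pi_wild": ("wild", params.pi_wild),
               "pi_japonica": ("japonica", params.pi_jap),
               "pi_indica": ("indica", params.pi_ind)}
    for name, (group, target) in targets.items():
        got = np.mean([rscan.pi_in_region(gm, st, group, (c, 1, L))
                       for c, L in params.chrom_lengths.items()])
        rows.append({"statistic": name, "target": target,
                     "realized": round(float(got), 5)})
    got = np.mean([rscan.dxy_in_region(gm, st, "japonica", "indica",
                                       (c, 1, L))
                   for c, L in params.chrom_lengths.items()])
    rows.append({"statistic": "dxy_jap_ind", "target": params.dxy_jap_ind,
                 "realized": round(float(got), 5)})
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "01_simulation_calibration.tsv", sep="\t",
              index=False)
    print(f"wrote {res.vcf_path} ({gm.n_sites} sites, "
          f"{gm.n_samples} samples) and truth BED with "
          f"{len(res.truth)} implanted regions")
    print(df.to_string(index=False))
    print("realized whole-genome rates sit slightly below target where "
          "implanted sweeps erase diversity; background windows match "
          "targets (tests/test_simulate.py).")


if __name__ == "__main__":
    sys.exit(main())
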