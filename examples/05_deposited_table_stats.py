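"""Analyze a deposited per-sample spreadsheet (CSV or XLSX).

Pass the path to a table with easting/northing, a cluster id and indicator
columns (header synonyms such as "%TC" or "MBC (ug C/g DW)" are mapped
automatically); with no argument, a synthetic 36-site table standing in
for such a deposit is generated and written to scratch form first.
"""

import sys
import tempfile
from pathlib import Path

import terrazone as tz
from terrazone import io as tio

if len(sys.argv) > 1:
    path = Path(sys.argv[1])
else:
    cfg = tz.SyntheticFieldConfig()
    _, truth = tz.generate_dem(cfg, seed=4)
    synthetic = tz.generate_sample_table(truth, None, cfg, n_per_zone=12, seed=5)
    synthetic = synthetic.rename(columns={
        "x": "Easting", "y": "Northing", "cluster": "Assigned Cluster",
        "mbc": "MBC (ug C/g DW)", "mbn": "MBN (ug N/g DW)",
        "total_c_pct": "%TC", "total_n_pct": "%TN",
    })
    path = Path(tempfile.gettempdir()) / "synthetic_deposit.csv"
    synthetic.to_csv(path, index=False)
    print(f"no table given; wrote a synthetic stand-in to {path}\n")

table = tio.read_sample_table(path)
print(f"parsed {len(table)} samples; "
      f"{table.groupby('cluster').size().to_dict()} per cluster")

indicators = [c for c in tio.INDICATOR_COLUMNS if c in table.columns]
for ind in indicators[:6]:
    ratios = tz.cluster_ratio_summary(table, ind, round_to=2)
    top = ratios.iloc[0]
    others = ", ".join(f"vs c{j}: {top[j]:.2f}" for j in ratios.columns[1:])
    print(f"{ind:>14}: cluster-{ratios.index[0]} mean ratio {others}")

print("\n(the same table feeds correlation_table / anova_by_cluster /"
      " bmu_representativeness, as in example 04)")
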