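"""Cluster LOEL summaries and read-across candidate selection on the bundled
published reference tables.

The 24-member glycol/alcohol cluster shows why a tight LOEL range matters:
its members share a toxicological profile but their LOELs span four orders
of magnitude, so it is not usable for quantitative read-across.  The
candidate table keeps only clusters whose geometric-mean/minimum ratio is
at most 5.
"""

from toxclust.clusterstats import (
    ClusterSummary,
    loel_summary,
    select_readacross_candidates,
    toxic_value,
)
from toxclust.datasets import (
    GLYCOL_ALCOHOL_CLUSTER_LOELS_MMOL,
    READACROSS_CANDIDATE_CLUSTERS,
)

gm, lo, hi, ratio = loel_summary(GLYCOL_ALCOHOL_CLUSTER_LOELS_MMOL)
print(f"glycol/alcohol cluster ({len(GLYCOL_ALCOHOL_CLUSTER_LOELS_MMOL)} "
      f"members): LOEL gm {gm:.2f} mmol/kg, range {lo}-{hi}, "
      f"gm/min ratio {ratio:.0f}")
print("-> ratio far above 5: qualitative grouping only\n")

summaries = [ClusterSummary(cluster_id=r["cluster"], n_members=0,
                            activity_fraction={}, loel_gm=r["gm"],
                            loel_min=r["lo"], loel_max=r["hi"],
                            ratio_gm_lower=r["gm"] / r["lo"],
                            ratio_max_min=r["hi"] / r["lo"])
             for r in READACROSS_CANDIDATE_CLUSTERS]
print("published candidate clusters, re-ranked by recomputed gm/min ratio:")
for s in select_readacross_candidates(summaries, max_ratio=5.5):
    print(f"  cluster {s.cluster_id:>3}: gm {s.loel_gm:.2f} mmol/kg, "
          f"ratio {s.ratio_gm_lower:.1f}")
print("\nfor these, the cluster gm LOEL (with an additional assessment "
      "factor of 5) can stand in for a missing point of departure")

# the per-compound toxic value condenses a profile to one number
print("\ntoxic value of profile (high, low, missing):",
      toxic_value([1.0, 0.0, float('nan')]), "(2 + 1 + 0)")
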