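"""One-call reduced-scale run of the complete analysis pipeline.

Simulation -> preprocessing -> markers -> behavior -> cluster permutation
statistics (four model families) -> joint LRTC x PSD model -> ERP arm, with
a JSON-serializable report.  Scale here is kept small so the example runs in
about a minute; raise n_subjects/duration_s/n_permutations for study scale.
"""

from eegate import RunConfig, run_full

cfg = RunConfig(seed=11, n_subjects=12, duration_s=180, n_permutations=200,
                channels=["C2", "C4", "CP2", "CP4", "CP6", "P4", "P6", "Pz"])
report = run_full(cfg)

ms = report.marker_summary
print(f"marker grand means: DFA {ms['dfa_grand_mean']:.3f}, "
      f"gamma {ms['gamma_grand_mean']:.3f}, rel alpha {ms['rel_alpha_mean']:.3f}")
for fid, res in report.cluster_results.items():
    n_sig = sum(c["significant"] for c in res["clusters"])
    print(f"model {fid}: {len(res['clusters'])} cluster(s), {n_sig} significant "
          f"(null 95th pct {res['null_95th']:.2f})")
print(f"interaction DFA x PSD: beta {report.interaction['dfa_psd']['beta']:+.4f} "
      f"(p={report.interaction['dfa_psd']['p']:.3f}), "
      f"VIFs {report.interaction['vif']}")
erp = report.erp_results
print(f"ERP: peak {1000 * erp['peak_latency_s']:.0f} ms, "
      f"P300 means {erp['p300_mean_by_condition']}")
print("Full details: report.to_json() / the persisted report.json when "
      "out_dir is set.")
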