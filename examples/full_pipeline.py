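"""Run the whole simulate -> count -> quantify -> kinetics -> stats pipeline.

Writes every stage's TSV plus a manifest into ./pipeline_demo and prints
the gene-funnel attrition, mirroring how a real run is reported.
"""

from tukinetics.pipeline import RunConfig, run_pipeline, worked_examples

cfg = RunConfig(n_genes=20, n_fragments=4000, n_iter=600, burn_in=150, seed=7)
manifest = run_pipeline(cfg, "pipeline_demo")

print(f"config hash: {manifest['config_hash']}")
for stage, count in manifest["funnel"].items():
    print(f"  {stage}: {count}")
print("outputs:", ", ".join(sorted(manifest["files"])))

print("\nworked arithmetic checks:")
worked_examples()
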