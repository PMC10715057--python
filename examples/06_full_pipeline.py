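"""Run the orchestrated analysis over two treatments and print the report.

Uses a reduced envelope count (99 simulations) so the demo finishes in a
couple of minutes; the study defaults are n_sims=199, rank=2.
"""
from gapregen import RunConfig, report, run_pipeline

config = RunConfig(
    treatments=("PYG", "PCK"),
    n_replicates=2,
    n_sims=99,
    seed=2024,
    out_dir="pipeline_demo",
)
bundle = run_pipeline(config)
print(report(bundle))
print(f"{len(bundle.manifest['outputs'])} files with checksums in "
      f"pipeline_demo/manifest.json")
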