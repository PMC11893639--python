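"""End-to-end pipeline run from a programmatic config.

Simulates every input, runs all five stages under one output directory, and
prints the manifest summary.  The same run is available from the shell as
`ranklap run --config run.yaml`.
"""

import tempfile

from ranklap.pipeline import RunConfig, run_full

with tempfile.TemporaryDirectory() as tmp:
    config = RunConfig(
        seed=4,
        out_dir=f"{tmp}/demo_run",
        simulate={"n_snps": 20_000, "n_genes": 800, "noncentrality": 4.0,
                  "shared_corr": 0.8},
        n_perm=2000, n_perm_gsea=200, sizes=[100, 200, 300, 400, 500],
    )
    manifest = run_full(config)
    print(f"stages completed: {manifest.stages}")
    for stage, secs in manifest.wall_clock.items():
        print(f"  {stage:12s} {secs:6.2f} s")
    print(f"output files checksummed: {len(manifest.checksums)}")
    print(f"warnings: {len(manifest.warnings)}")
print(
    "\nThe manifest records a SHA-256 checksum per output file; re-running\n"
    "the same config and seed reproduces every checksum bit-for-bit."
)
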