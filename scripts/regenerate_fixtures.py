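"""Regenerate the committed test fixture bundle and golden outputs.

Run from the repository root:

    python scripts/regenerate_fixtures.py

The bundle is fully determined by its seed; goldens are the pipeline's
own output on the bundle (generated once, then held fixed to pin
byte-level reproducibility).
"""

import shutil
import sys
import os
import tempfile
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from sipscreen.pipeline import RunConfig, run_pipeline  # noqa: E402
from sipscreen.simulate import write_fixture_bundle  # noqa: E402

SEED = 20230211


def main() -> None:
    data = ROOT / "tests" / "data"
    fixtures = data / "fixtures"
    golden = data / "golden"
    if fixtures.exists():
        shutil.rmtree(fixtures)
    write_fixture_bundle(fixtures, seed=SEED)

    # run the pipeline from a temp dir with relative paths (matching how
    # the golden test invokes it) so the manifest is location-independent
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        shutil.copytree(fixtures, tmp / "fixtures")
        cwd = os.getcwd()
        os.chdir(tmp)
        try:
            cfg = RunConfig(
                gradients="fixtures/gradients.tsv",
                fractions="fixtures/fractions.tsv",
                counts="fixtures/counts.tsv",
                outdir="out",
                seed=SEED,
            )
            run_pipeline(cfg)
        finally:
            os.chdir(cwd)
        if golden.exists():
            shutil.rmtree(golden)
        golden.mkdir(parents=True)
        for name in ("ef_table.tsv", "manifest.json"):
            shutil.copy(tmp / "out" / name, golden / name)
    print(f"wrote {fixtures} and {golden}")


if __name__ == "__main__":
    main()
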