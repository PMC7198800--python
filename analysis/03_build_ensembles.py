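"""Build the per-strain gapfilled network ensembles.

Each ensemble member starts from the degraded draft network and is trained
by positive gapfilling (minimum-cardinality MILP additions from the
universal database) on a random subset of growth-supporting substrates,
then negative trimming on a random subset of non-supporting ones.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from config import CONFIG, OUTDIR

from nitrofba.pipeline import Pipeline


def main() -> None:
    pipe = Pipeline(CONFIG, OUTDIR)
    pipe.run(["simulate", "build-ensemble"])
    for ens_dir in sorted((OUTDIR / "build_ensemble").glob("ensemble_*")):
        manifest = json.loads((ens_dir / "records.json").read_text())
        added = [len(r["added_reaction_ids"]) for r in manifest["records"]]
        removed = [len(r["removed_reaction_ids"]) for r in manifest["records"]]
        unresolved = sum(len(r["unresolved_negatives"]) for r in manifest["records"])
        print(f"{ens_dir.name}: {manifest['size']} members, "
              f"additions per member {min(added)}-{max(added)}, "
              f"trimmed {sum(removed)} total, "
              f"{unresolved} unresolvable negatives")


if __name__ == "__main__":
    main()
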