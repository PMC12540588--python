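"""The file-based route: CSVs in, result tables out.

Equivalent to `anomviol simulate` + `anomviol run` from the shell; useful
when weather and incident extracts arrive as files.
"""

import tempfile
from pathlib import Path

from anomviol import make_fixture, run_study
from anomviol.report import write_outputs

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    make_fixture("khayelitsha-like", seed=11, out_dir=tmp)

    run = run_study(
        {"khayelitsha": (tmp / "weather_khayelitsha.csv", tmp / "incidents_khayelitsha.csv")},
        "2011-01-01", "2015-12-31",
    )
    written = write_outputs(run, tmp / "results")
    print(f"panel: {len(run.panels['khayelitsha'])} days")
    print(f"comparisons run: {len(run.results.comparisons)}")
    print("files written:")
    for path in written:
        print(f"  {path.name}")

# The panel CSV carries one row per study day with counts, weather and all
# derived labels; the comparison CSVs hold one row per group and per Tukey
# contrast across the whole battery (anomaly, exposure, weekend, crossed,
# and disadvantaged-substream reruns).
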