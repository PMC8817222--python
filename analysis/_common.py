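"""Shared plumbing for the analysis drivers: load the simulated registry
written by 01_simulate.py and apply the standard cleaning pipeline."""

import datetime as dt
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from eirkit.data_model import TABLE_NAMES, clean_bundle, read_registry  # noqa: E402
from eirkit.schedule import default_schedule  # noqa: E402

DATA_DIR = ROOT / "results" / "data"
RESULTS = ROOT / "results"
CENSUS = dt.date(2019, 12, 31)


def load_bundle():
    paths = {name: DATA_DIR / f"{name}.csv" for name in TABLE_NAMES}
    missing = [p for p in paths.values() if not p.exists()]
    if missing:
        raise SystemExit("registry tables not found — run "
                         "analysis/01_simulate.py first")
    return read_registry(paths)


def load_clean(include_back_entered: bool = False):
    bundle = load_bundle()
    cleaned, log = clean_bundle(bundle,
                                include_back_entered=include_back_entered)
    return bundle, cleaned, log


def emit(df, name: str) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / f"{name}.csv"
    df.to_csv(path, index=False)
    print(f"  wrote {path.relative_to(ROOT)} ({len(df)} rows)")
    return path
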