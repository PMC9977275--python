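"""Gene presence calls and gain/loss counts between the two visits.

Reads results/cohort/, writes results/gain_loss.tsv, and compares the called
loss counts with the simulator's planted strain-level events.
"""

from pathlib import Path

import pandas as pd

from microdiv import read_cohort
from microdiv.genes import gain_loss_table

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    tables = read_cohort(ROOT / "cohort")
    gl = gain_loss_table(tables.genes, tables.abundance.meta_frame())
    gl.to_csv(ROOT / "gain_loss.tsv", sep="\t", index=False)
    events = pd.read_csv(ROOT / "cohort" / "truth_events.tsv", sep="\t")
    print(
        f"{len(gl)} host × species pairs; called {gl.n_lost.sum()} losses and "
        f"{gl.n_gained.sum()} gains; simulator planted "
        f"{(events.kind == 'loss').sum()} strain-level losses (multi-strain "
        "hosts hide losses that only remove one carrier, so called < planted)"
    )
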