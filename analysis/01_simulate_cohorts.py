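#!/usr/bin/env python
"""Generate the synthetic study datasets.

Emulates the study design: a gerbil cohort of 7 animals with tone sweeps at
30-80 dB SPL (sensitive and postmortem) plus a 10-animal click cohort at
70/80/90 dB-p, and a 5-animal mouse tone cohort. Writes everything in the
package's TSV dialects under results/data/.
"""

from pathlib import Path

from corti import io as cio
from corti.synth import gerbil_params, make_cohort, mouse_params

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    gerbil = make_cohort(
        gerbil_params(), 7, levels=(50, 60, 70, 80), seed=SEED,
        states=("sensitive", "postmortem"),
    )
    cio.write_spectra(gerbil.spectra, OUT / "gerbil_spectra.tsv")
    cio.save_params(gerbil.params, OUT / "gerbil_params.yaml")

    clicks = make_cohort(
        gerbil_params(), 10, levels=(), seed=SEED + 6,
        states=("sensitive", "postmortem"), click_levels=(70.0, 80.0, 90.0),
    )
    cio.write_timeseries(clicks.clicks, OUT / "gerbil_clicks.tsv")

    mouse = make_cohort(mouse_params(), 5, levels=(50, 60, 70, 80), seed=SEED + 1)
    cio.write_spectra(mouse.spectra, OUT / "mouse_spectra.tsv")
    cio.save_params(mouse.params, OUT / "mouse_params.yaml")

    print(f"gerbil: {len(gerbil.spectra)} spectra "
          f"({len({s.animal_id for s in gerbil.spectra})} animals, sensitive+postmortem)")
    print(f"clicks: {len(clicks.clicks)} records "
          f"({len({c.animal_id for c in clicks.clicks})} animals x 3 levels x 2 states x RL/BM)")
    print(f"mouse:  {len(mouse.spectra)} spectra")
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
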