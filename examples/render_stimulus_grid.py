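"""Render oblique-grating illusion stimuli and inspect the grid.

The default grid crosses 12 bar hues with 6 diamond widths (5-10 px)
and the two mirror positional settings: 144 stimuli, each a 560 x 160
image of four physically horizontal bars that appear tilted.
"""

from pathlib import Path

from illusionprobe import enumerate_stimulus_grid, render_illusion

out = Path("scratch/example_stimuli")
out.mkdir(parents=True, exist_ok=True)

grid = enumerate_stimulus_grid()
print(f"{len(grid)} stimuli in the default grid")

# render one stimulus per hue at width 7, setting I
for spec in grid:
    if spec.diamond_width_px == 7 and spec.positional_setting == "I":
        img = render_illusion(spec)
        img.save(out / f"{spec.stimulus_id}.png")
        print(f"  {spec.stimulus_id:22s} sha256 {img.sha256()[:12]}")

print(f"\nwrote 12 PNGs to {out}/")
print("Every bar in every image is physically horizontal; any apparent")
print("tilt is the illusion the classifier will later be probed with.")
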