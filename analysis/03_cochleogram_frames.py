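#!/usr/bin/env python
"""Frequency-frame placement along a reconstructed cochlear spiral.

Builds a digitised spiral-bundle trace of realistic length (~9.4 mm,
rendered as an unwinding spiral in µm image coordinates), maps the six
analysis frequencies (2.8-45.2 kHz) to arc positions with the rat
place-frequency map, and writes the frame table.  Arc positions use the
measured trace length; frequency order equals position order from apex to
base.
"""

import json
import sys
from pathlib import Path

import numpy as np

RESULTS = Path(__file__).resolve().parent.parent / "results"


def make_spiral_trace(target_length_um: float = 9400.0, n: int = 2000):
    """A 2.25-turn Archimedean spiral scaled to the target arc length."""
    from efferentquant.cochleogram import SpiralTrace

    theta = np.linspace(0, 2.25 * 2 * np.pi, n)
    r = 150.0 + 90.0 * theta
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    t = SpiralTrace(pts)
    return SpiralTrace(pts * (target_length_um / t.length))


def main() -> None:
    from efferentquant.cochleogram import RAT_MAP, locate_frequency_frames
    from efferentquant.synthetic import ANALYSIS_FREQUENCIES_KHZ

    trace = make_spiral_trace()
    print(f"trace length: {trace.length:.1f} µm (reference 9,400 µm)")
    frames = locate_frequency_frames(
        trace, ANALYSIS_FREQUENCIES_KHZ, RAT_MAP, frame_size_um=112.0
    )
    print(f"{'kHz':>6} {'arc µm':>9} {'fraction':>9}")
    for fr in frames:
        print(f"{fr.frequency_khz:6.1f} {fr.arc_position_um:9.1f} "
              f"{fr.arc_position_um / trace.length:9.3f}")
    out = RESULTS / "frequency_frames.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(
        json.dumps(
            {
                "trace_length_um": trace.length,
                "frames": [
                    {
                        "frequency_khz": fr.frequency_khz,
                        "arc_position_um": fr.arc_position_um,
                        "center_um": fr.center,
                        "bounds_um": fr.bounds,
                    }
                    for fr in frames
                ],
            },
            indent=2,
        )
    )
    print(f"wrote {out}")


if __name__ == "__main__":
    sys.exit(main())
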