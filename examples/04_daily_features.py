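"""Fuse one labeled day into energy intensities and dwell occurrences.

Builds a miniature hand-made day (sitting in the resident room, a therapy
block, a bathroom visit), then prints the per-category energy intensities
(kappa-scaled time-weighted mean MAD), the sedentary fraction, and the
occurrence counts under the strict 40-s dwell rule.
"""

import pandas as pd

from wardsense import count_occurrences, segment_locations, summarize_day

windows = pd.DataFrame(
    {
        "mad": [0.012] * 6 + [0.022] * 6 + [0.020] * 3,
        "duration_s": 10.0,
        "worn": True,
        "activity": ["sitting"] * 6 + ["standing"] * 6 + ["standing"] * 3,
        "location": ["resident_room"] * 6 + ["therapy_area"] * 6 + ["bathroom"] * 3,
    }
)
locations = windows["location"].tolist()
intervals = segment_locations(locations, window_duration_s=10.0)
occ = {
    loc: count_occurrences(intervals, loc)
    for loc in ("resident_room", "therapy_area", "bathroom")
}
vec = summarize_day(windows, "P1", 0, occurrences=occ)

print(f"wear time          {vec.wear_time_s:6.0f} s")
print(f"overall EI         {vec.overall_EI:6.1f}   (kappa x mean MAD of the day)")
print(f"resident-room EI   {vec.resident_room_EI:6.1f}")
print(f"therapy-room EI    {vec.therapy_room_EI:6.1f}")
print(f"sitting EI         {vec.sitting_EI:6.1f}")
print(f"standing EI        {vec.standing_EI:6.1f}")
print(f"sedentary fraction {vec.sedentary_fraction:6.2f}")
print("occurrences (>40 s continuous):", vec.occurrences)
print("\nEach stay longer than 40 s counts once; the 30-s bathroom visit is")
print("below the dwell threshold and contributes no occurrence.")
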