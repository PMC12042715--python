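"""Bundled example data.

``SAMPLE_LOG_CSV`` is an 18-attempt excerpt from a published single-operator
end-to-end anastomosis training log, transcribed into the package's CSV
schema.  Attempts 6, 13, 14 and 16 were aborted by a major mistake (total
score 5) and therefore carry a total time of 0 with no stage times.

The companion constant ``FULL_TRIAL_MAJOR_ATTEMPTS`` gives a 132-attempt
major-mistake placement consistent with the cumulative major-mistake-average
(MMA) values reported for the same trial: the first five majors fall at
attempts 6, 13, 14, 16 and 19 (MMA 5/19 ≈ 0.263 at the peak), one more by
attempt 36 (6/36 ≈ 0.167), four more by attempt 85 (10/85 ≈ 0.118) and two
more by attempt 132 (12/132 ≈ 0.091).  Only the first 18 attempts of the raw
table are public; the placements after attempt 19 inside each period are
otherwise arbitrary and are marked synthetic.
"""

from __future__ import annotations

import io

from .records_io import AttemptRecord, read_attempts

__all__ = ["SAMPLE_LOG_CSV", "load_sample_attempts", "FULL_TRIAL_MAJOR_ATTEMPTS"]

SAMPLE_LOG_CSV = """\
attempt,date,stage1_mistakes,stage2_mistakes,stage3_mistakes,total_score,stage1_time,stage2_time,stage3_time,total_time
1,"April 18, 2024",-,-,1,1,776,203,"1,159","2,138"
2,"April 19, 2024",-,1,1,2,"1,002",859,752,"2,613"
3,"April 18, 2024",-,-,-,0,408,562,901,"1,871"
4,"April 20, 2024",-,1,-,0,484,648,"1,925","3,057"
5,"April 24, 2024",-,-,-,0,619,452,"1,865","2,936"
6,"April 24, 2024",-,5,-,5,-,-,-,0
7,"April 25, 2024",-,-,1,1,690,646,"1,458","2,794"
8,"April 24, 2024",-,-,1,1,404,397,840,"1,641"
9,"April 26, 2024",-,-,2,1,435,135,"1,028","1,598"
10,"April 26, 2024",-,-,-,0,446,946,690,"2,082"
11,"April 26, 2024",-,-,-,0,519,593,822,"1,934"
12,"April 29, 2024",-,-,-,1,246,505,"1,188","1,939"
13,"April 30, 2024",5,-,-,5,-,-,-,0
14,"April 30, 2024",-,5,-,5,-,-,-,0
15,"April 30, 2024",-,-,-,0,472,508,962,"1,942"
16,"May 2, 2024",-,5,-,5,-,-,-,0
17,"May 2, 2024",-,1,1,2,711,648,"1,079","2,438"
18,"May 2, 2024",-,1,-,1,366,573,"1,039","1,978"
"""

#: Synthetic-after-attempt-19 reconstruction of the full trial's major-mistake
#: attempt numbers (see module docstring).
FULL_TRIAL_MAJOR_ATTEMPTS = (6, 13, 14, 16, 19, 27, 45, 58, 70, 82, 101, 120)

#: Attempt count of the full trial the sample log is excerpted from.
FULL_TRIAL_N_ATTEMPTS = 132


def load_sample_attempts() -> list[AttemptRecord]:
    """Parse the bundled 18-attempt sample log."""
    return read_attempts(io.StringIO(SAMPLE_LOG_CSV))
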