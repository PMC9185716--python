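"""Score one respondent on the full instrument and the derived screener.

Builds a single 34-item response, scores the full scale (sum of frequency
codes, positive at >= 6), derives the three-item screener from it, and shows
how the screener classifies at each cutpoint.
"""

import marsha_screen as ms

# a respondent endorsing a few acts: codes are 0 ("0 times"), 1 ("1-3"),
# 2 ("4-10"), 3 ("more than 10 times"); None = skipped question
items = {iid: 0 for iid in ms.DEFAULT_SCHEMA.item_ids}
items["int_yelled"] = 3          # yelled/screamed/swore, more than 10 times
items["soc_trapped"] = 1         # felt unable to break up, 1-3 times
items["priv_looked_phone"] = 2   # looked through phone, 4-10 times
items["soc_jealous"] = None      # skipped

ref = ms.score_marsha(items)
print(f"full-scale score: {ref.score} (missing items: {ref.n_missing})")
print(f"reference classification (score >= {ref.cutpoint}): "
      f"{'DA-positive' if ref.positive else 'DA-negative'}")

screener = ms.derive_marsha_c_from_marsha(items)
print(f"\nscreener endorsements: yelled={screener.yelled}, "
      f"pressured_photo={screener.pressured_photo}, trapped={screener.trapped}")
for cut in (1, 2, 3):
    cls = ms.score_marsha_c(screener, cutpoint=cut)
    print(f"  cutpoint >= {cut}: score {cls.score} -> "
          f"{'positive' if cls.positive else 'negative'}")

# This respondent sums to 6 points, so the reference calls them a survivor;
# the screener (2 of 3 acts endorsed) agrees at cutpoints 1 and 2.
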