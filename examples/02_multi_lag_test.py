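"""Multi-lag TTS test: detecting coupling when the delay is only known
to lie in a range.

The coupling delay here is 2 steps, but suppose we only know it is
somewhere between 0 and 4. Testing each lag at alpha/m (Bonferroni) keeps
validity; the radius 99 = 5/0.05 - 1 makes the corrected threshold exactly
attainable.
"""

from ttshift import make_statistic, multi_lag_tts
from ttshift.systems import simulate_coupled_ar

x, y = simulate_coupled_ar(400, beta=0.5, coupling_lag=2, seed=42)
res = multi_lag_tts(x, y, r=99, stat=make_statistic("pearson"),
                    lags=[0, 1, 2, 3, 4], alpha=0.05)

for t in res.per_lag:
    flag = "*" if t.reject else " "
    print(f"lag {t.lag}:  B={t.B:3d}  u={t.u:.4f} {flag}")
print(f"family decision (any u <= 0.05/5 = 0.01): reject={res.reject}")

# The lag-2 row (and usually its neighbours) carries the signal; lags far
# from the true delay have large B because the correlation peak sits away
# from delta = 0.
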