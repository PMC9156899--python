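"""Evaluate the utility models and the reported-scale transforms.

Expected utility of a lottery is [p - beta*A/2] * sign(v)|v|^alpha; a
delayed reward is worth v / (1 + kappa*d); utility differences map to choice
probabilities through a logistic with inverse temperature gamma.
"""

from emaecon import models, tasks

params = models.RiskParams(alpha=0.8, beta=0.6, gamma=4.0)
trial = tasks.RiskTrial("gain", guaranteed=0.50, v=6.60, p=0.50, A=0.50)

eu_lottery = models.expected_utility(trial, params)
eu_safe = models.safe_utility(trial.guaranteed, params.alpha)
p_lottery = models.prob_choose_lottery(eu_lottery, eu_safe, params.gamma)
print(f"ambiguous $6.60 lottery: EU = {eu_lottery:.3f} vs safe {eu_safe:.3f} "
      f"-> P(choose lottery) = {p_lottery:.3f}")

u_now = models.discounted_utility(1.50, 0, kappa=0.05)
u_later = models.discounted_utility(5.50, 21, kappa=0.05)
p_later = models.prob_choose_delayed(u_later, u_now, gamma=1.5)
print(f"$1.50 now vs $5.50 in 3 weeks at kappa=0.05/day: "
      f"U = {u_now:.2f} vs {u_later:.2f} -> P(wait) = {p_later:.3f}")

# reported scales orient 'larger = more tolerant' in both gain and loss frames
risk_tol, amb_tol = models.risk_to_reported(params.alpha, params.beta, "gain")
print(f"reported: risk tolerance {risk_tol:+.2f} (alpha-1), "
      f"ambiguity tolerance {amb_tol:+.2f} (-beta); both negative = averse")
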