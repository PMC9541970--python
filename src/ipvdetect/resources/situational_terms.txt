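# IPV situational terms (23): phrases derived from the IPV literature,
# risk-assessment instruments, and clinician expertise. One phrase per line.
domestic violence
intimate partner violence
spouse abuse
battered woman
domestic abuse
spousal abuse
intimate partner abuse
battered
violence against women
domestic assault
domestic dispute
problems with spouse or partner
maltreatment by spouse or partner
neglect and abandonment by spouse or partner
assault by husband
assault by partner
assault by wife
assault by spouse
assault by boyfriend
assault by girlfriend
assault by significant other
referral to partnership against domestic violence
resources or shelter for domestic violence
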