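# IPV extended situational terms (49): mechanism-specific phrases mined from
# confirmed IPV encounters (attack / strike / strangle variants, abbreviations).
# "violence against women" also appears in the situational tier.
intimate partner homicide
femicide
intimate partner death
spousal homicide
ipv
dv
domestic violence resources
assault by so
assault by domestic partner
assault by ex
assault by bf
assault by gf
strangle by boyfriend
strangle by girlfriend
strangle by wife
strangle by husband
strangle by spouse
strangle by domestic partner
strangle by partner
strangle by significant other
strangle by so
strangle by ex
strangle by bf
strangle by gf
strike by boyfriend
strike by girlfriend
strike by wife
strike by husband
strike by spouse
strike by domestic partner
strike by partner
strike by significant other
strike by so
strike by ex
strike by bf
strike by gf
attack by boyfriend
attack by girlfriend
attack by wife
attack by husband
attack by spouse
attack by domestic partner
attack by partner
attack by significant other
attack by so
attack by ex
attack by bf
attack by gf
violence against women
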