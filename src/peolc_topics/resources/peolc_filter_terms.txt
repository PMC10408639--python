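palliativetherapy
palliativeservice
palliativerehabilitation
palliativemedicine
palliativecareawareness
palliativecare
palliative therapy
palliative service
palliative rehabilitation
palliative medicine
palliative care
palliative assessment
palliative patient
palliative team
palliative staff
palliative_therapy
palliative_medicine
palliative_care
pallcare
palcare
pallmedicine
pallonc
pall care
oncology care
supportive_care
advanced care
terminal care
respite care
bereavement care
hospicecare
hospice care
hospice
eolcare
eolc
eol support
eol care
#eol
end of life
endoflifesupport
endoflifecare
end of life support
end of life care
end_of_life_care
ehospice
comfortcare
comfort care
cancercare
cancer care
supportivecare
supportive care
NCPGuidelines
NCP_Guidelines
NCPGuidelines
NCP Guidelines
hpmglobal
#hpm
#hapc
hospicecareweek
pallicovid
covpall
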