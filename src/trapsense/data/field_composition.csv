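category,group,species,trial1,trial2
mosquito,target,Culex pipiens,1261,1387
mosquito,target,Aedes albopictus,270,543
mosquito,target,Aedes caspius,39,0
mosquito,non_target,Culiseta longiareolata,94,39
mosquito,non_target,Coquillettidia richiardii,1,0
other_insect,non_target,Non-culicidae insects,3188,2125
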