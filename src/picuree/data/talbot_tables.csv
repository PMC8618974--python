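id,abscissa,ree_kcal_day,citation
talbot_weight,3,150,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,5,270,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,7,400,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,9,500,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,11,600,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,13,650,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,15,710,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,17,780,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,19,830,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,21,880,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,25,1020,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,29,1120,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,33,1210,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,37,1300,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,41,1350,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,45,1410,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,49,1470,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,53,1530,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,57,1590,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,61,1640,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,65,1700,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,69,1750,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,73,1800,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,77,1850,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,81,1900,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_weight,85,1950,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by weight)"
talbot_height,50,140,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,55,200,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,60,270,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,65,330,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,70,400,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,75,455,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,80,500,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,85,550,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,90,600,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,95,650,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,100,700,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,105,740,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,110,780,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,115,835,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,120,890,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,125,940,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,130,990,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,135,1045,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,140,1100,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,145,1175,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,150,1250,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,155,1325,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,160,1400,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,165,1475,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,170,1550,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,175,1620,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
talbot_height,180,1690,"Talbot FB. Am J Dis Child 1938;55:455-459 (basal metabolism by height; sex-averaged transcription)"
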