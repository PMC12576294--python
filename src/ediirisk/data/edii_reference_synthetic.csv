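component,unit,mean,sd,weight
alcohol,g,6.5,5.9,-0.278
vitamin_b12,ug,2.6,1.2,0.106
vitamin_b6,mg,0.9,0.4,-0.365
beta_carotene,ug,1900.0,1300.0,-0.584
caffeine,g,0.04,0.03,-0.110
carbohydrate,g,136.0,22.0,0.097
cholesterol,mg,140.0,55.0,0.110
total_fat,g,36.0,7.5,0.298
fiber,g,9.4,2.9,-0.663
folic_acid,ug,140.0,48.0,-0.190
garlic,g,2.1,1.8,-0.412
iron,mg,6.3,1.8,0.032
magnesium,mg,155.0,38.0,-0.484
mufa,g,13.0,3.4,-0.009
niacin,mg,12.0,3.5,-0.246
omega3,g,0.8,0.5,-0.436
omega6,g,4.9,1.9,-0.159
onion,g,17.0,12.0,-0.301
protein,g,38.0,6.9,0.021
pufa,g,7.2,2.4,-0.337
riboflavin,mg,0.9,0.3,-0.068
saturated_fat,g,13.0,3.9,0.373
selenium,ug,34.0,13.0,-0.191
tea,g,210.0,180.0,-0.536
thiamin,mg,0.8,0.3,-0.098
vitamin_a,RE,420.0,240.0,-0.401
vitamin_c,mg,55.0,28.0,-0.424
vitamin_d,ug,2.5,1.6,-0.446
vitamin_e,mg,4.7,1.8,-0.419
zinc,mg,4.8,1.3,-0.313
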